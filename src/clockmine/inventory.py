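"""Aggregation of accepted homologs into clock inventories and summaries.

Builds per-strain clock systems (factor sets and copy numbers), genus-level
mean-similarity tables, condensed copy-number profiles and protein-length
distributions. Strains without at least one KaiC-family homolog are dropped:
KaiC is the core of the oscillator, so its absence disqualifies a strain from
the clock inventory.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from clockmine.datatypes import (
    ClockSystem,
    GenusSummary,
    LengthRecord,
    RBHPair,
    TaxonGroup,
    TAXON_GROUP_ORDER,
)
from clockmine.factors import DEFAULT_MERGE_MAP, KAIC_FAMILY, QUERY_FACTORS, merge_label, validate_merge_map

logger = logging.getLogger(__name__)


def build_inventory(
    rbh_pairs: Sequence[RBHPair],
    factor_merge_map: Mapping[str, str] | None = None,
    organism_meta: Mapping[str, tuple[str, TaxonGroup | str]] | None = None,
    require_kaic: bool = True,
) -> list[ClockSystem]:
    """Gather subtype-labelled homologs into one clock system per strain.

    Copy counts are the number of distinct accepted subjects per (merged)
    factor label. With ``require_kaic`` (default), strains lacking every
    KaiC-family factor are dropped. ``organism_meta`` optionally supplies
    ``organism -> (genus, taxon_group)``.
    """
    merge_map = dict(DEFAULT_MERGE_MAP if factor_merge_map is None else factor_merge_map)
    validate_merge_map(merge_map)
    kaic_labels = {merge_label(f, merge_map) for f in KAIC_FAMILY}

    counts: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for pair in rbh_pairs:
        if not pair.subtype:
            raise ValueError(f"pair {pair.subject_id} has no subtype label assigned")
        label = merge_label(pair.subtype, merge_map)
        counts[pair.subject_organism][label].add(pair.subject_id)

    systems: list[ClockSystem] = []
    for strain in sorted(counts):
        copy_counts = {f: len(ids) for f, ids in counts[strain].items()}
        if require_kaic and not (kaic_labels & set(copy_counts)):
            logger.info("build_inventory: %s has no KaiC-family homolog; dropped", strain)
            continue
        genus, group = "", TaxonGroup.OTHER
        if organism_meta and strain in organism_meta:
            genus, group = organism_meta[strain]
            group = TaxonGroup.coerce(group)
        elif strain:
            genus = strain.split()[0]
        systems.append(
            ClockSystem(strain=strain, copy_counts=copy_counts, genus=genus, taxon_group=group)
        )
    return systems


def genus_mean_similarity(
    rbh_pairs: Sequence[RBHPair],
    organism_meta: Mapping[str, tuple[str, TaxonGroup | str]] | None = None,
    factor_merge_map: Mapping[str, str] | None = None,
    kaic_labels: frozenset[str] = KAIC_FAMILY,
) -> list[GenusSummary]:
    """Per-genus arithmetic mean of percent similarity for each factor.

    A factor with no accepted hit in a genus is absent from that genus's
    summary (missing, not zero). Genera are ordered by taxon group and then
    by descending KaiC-family mean similarity, matching the standard
    homolog-distribution layout.
    """
    merge_map = dict(DEFAULT_MERGE_MAP if factor_merge_map is None else factor_merge_map)
    rows = []
    for pair in rbh_pairs:
        genus, group = "", TaxonGroup.OTHER
        if organism_meta and pair.subject_organism in organism_meta:
            genus, group = organism_meta[pair.subject_organism]
            group = TaxonGroup.coerce(group)
        elif pair.subject_organism:
            genus = pair.subject_organism.split()[0]
        rows.append(
            {
                "genus": genus,
                "taxon_group": group,
                "organism": pair.subject_organism,
                "factor": merge_label(pair.subtype, merge_map),
                "similarity": pair.forward_hit.percent_similarity,
            }
        )
    if not rows:
        return []
    table = pd.DataFrame(rows)
    merged_kaic = {merge_label(f, merge_map) for f in kaic_labels}
    summaries = []
    for (genus, group), sub in table.groupby(["genus", "taxon_group"], sort=False):
        mean_sim = sub.groupby("factor")["similarity"].mean().to_dict()
        kaic_sim = np.mean([v for f, v in mean_sim.items() if f in merged_kaic] or [np.nan])
        summaries.append(
            (
                TAXON_GROUP_ORDER.index(group),
                -(kaic_sim if np.isfinite(kaic_sim) else -np.inf),
                GenusSummary(
                    genus=genus,
                    taxon_group=group,
                    n_genomes=sub["organism"].nunique(),
                    mean_similarity=mean_sim,
                ),
            )
        )
    summaries.sort(key=lambda t: (t[0], t[1], t[2].genus))
    return [s for _, _, s in summaries]


def copy_number_profile(
    inventories: Sequence[ClockSystem],
    factors: Sequence[str] | None = None,
    condense_above: int = 5,
) -> pd.DataFrame:
    """Strain x factor matrix of copy numbers, condensed above a cap.

    Counts 0..``condense_above`` are reported exactly; larger counts are
    collapsed into the single category ``">5"`` (for the default cap).
    """
    if factors is None:
        seen = sorted({f for inv in inventories for f in inv.copy_counts})
        factors = [f for f in QUERY_FACTORS if f in seen] + [
            f for f in seen if f not in QUERY_FACTORS
        ]
    label = f">{condense_above}"

    def condense(count: int) -> str:
        return label if count > condense_above else str(count)

    data = {
        inv.strain: [condense(inv.copy_counts.get(f, 0)) for f in factors]
        for inv in inventories
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(factors))


def length_distribution(
    records: Sequence[LengthRecord],
    pair: tuple[str, str],
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Joint length table for a factor pair plus per-factor empirical CDFs.

    The joint table has one row per organism possessing both factors (using
    each organism's longest copy per factor); organisms with only one factor
    still contribute to that factor's marginal CDF.
    """
    if not records:
        raise ValueError("length_distribution requires at least one record")
    fx, fy = pair
    table = pd.DataFrame(
        [
            {
                "factor": r.factor,
                "organism": r.organism,
                "taxon_group": r.taxon_group.value,
                "length": r.length,
            }
            for r in records
        ]
    )
    cdfs: dict[str, pd.DataFrame] = {}
    for factor, sub in table.groupby("factor"):
        lengths = np.sort(sub["length"].to_numpy())
        cdfs[factor] = pd.DataFrame(
            {"length": lengths, "cdf": np.arange(1, len(lengths) + 1) / len(lengths)}
        )
    per_org = (
        table.groupby(["organism", "taxon_group", "factor"])["length"].max().unstack("factor")
    )
    joint_rows = []
    if fx in per_org.columns and fy in per_org.columns:
        both = per_org.dropna(subset=[fx, fy])
        for (organism, group), row in both.iterrows():
            joint_rows.append(
                {
                    "organism": organism,
                    "taxon_group": group,
                    f"length_{fx}": int(row[fx]),
                    f"length_{fy}": int(row[fy]),
                }
            )
    joint = pd.DataFrame(
        joint_rows,
        columns=["organism", "taxon_group", f"length_{fx}", f"length_{fy}"],
    )
    return joint, cdfs
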