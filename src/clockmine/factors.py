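"""Clock-factor label sets, the default query panel and label merging.

The homology screen uses 23 query proteins: the 17 clock-related factors of
*Synechococcus elongatus* PCC 7942 plus the three diverged KaiB and KaiC
paralogs of *Synechocystis* sp. PCC 6803 (KaiB1-3, KaiC1-3). Because the
Synechococcus KaiB/KaiC queries and the Synechocystis KaiB1/KaiC1 queries
recover near-identical homolog sets, their labels are merged for downstream
statistics, leaving 21 distinct factors. Both the query panel and the merge
map are configurable.
"""

from __future__ import annotations

# Input, core and output factors of the Synechococcus 7942 clock network.
SYNECHOCOCCUS_FACTORS = (
    "KaiA",
    "KaiB",
    "KaiC",
    "Pex",
    "LdpA",
    "CikA",
    "SasA",
    "RpaA",
    "RpaB",
    "LabA",
    "LalA",
    "Crm",
    "CpmA",
    "NhtA",
    "PrkE",
    "IrcA",
    "CdpA",
)

# Diverged paralog subgroups named after the three Synechocystis 6803 copies.
SYNECHOCYSTIS_PARALOGS = ("KaiB1", "KaiB2", "KaiB3", "KaiC1", "KaiC2", "KaiC3")

#: The full 23-protein query panel.
QUERY_FACTORS = SYNECHOCOCCUS_FACTORS + SYNECHOCYSTIS_PARALOGS

#: Default label merge: Synechococcus KaiB/KaiC fold into the KaiB1/KaiC1
#: subgroups, reducing the 23 query labels to 21 analysis factors.
DEFAULT_MERGE_MAP = {"KaiB": "KaiB1", "KaiC": "KaiC1"}

#: The 21 factors tested for co-occurrence (post-merge), in panel order.
ANALYSIS_FACTORS = tuple(
    f for f in QUERY_FACTORS if f not in DEFAULT_MERGE_MAP
)

#: KaiC-family labels; a strain is retained only if it has >= 1 of these.
KAIC_FAMILY = frozenset({"KaiC", "KaiC1", "KaiC2", "KaiC3"})


def merge_label(label: str, merge_map: dict[str, str] | None = None) -> str:
    """Collapse a factor label through the (possibly user-supplied) merge map."""
    m = DEFAULT_MERGE_MAP if merge_map is None else merge_map
    return m.get(label, label)


def validate_merge_map(merge_map: dict[str, str], known: tuple[str, ...] = QUERY_FACTORS) -> None:
    """Raise ``ValueError`` if the merge map references unknown factor labels."""
    unknown = [k for k in list(merge_map) + list(merge_map.values()) if k not in known]
    if unknown:
        raise ValueError(f"merge map references unknown factor labels: {sorted(set(unknown))}")
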