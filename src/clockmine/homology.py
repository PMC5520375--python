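"""Reciprocal best-hit homology screening.

The screen follows the classical two-pass design: a forward search of each
clock-factor query against every subject proteome keeps the best hits at a
stringent e-value (1e-5), and each subject is then searched back against the
query genome at a permissive e-value (10); a subject is accepted only when
its best reverse hit is the original query.

Instead of a word-seeded heuristic, pairwise scores come from exact
Smith-Waterman local alignment with affine gaps (BLOSUM62, gap open 11,
extend 1), which is bit-reproducible at desk scale. An adapter for BLAST
tabular output (``outfmt 6``) lets precomputed searches be substituted at
scale. E-values use the Karlin-Altschul formula ``E = K * m * n * exp(-lambda*S)``
with the published gapped-BLOSUM62 constants; they will not numerically match
BLAST's composition-adjusted values, which is immaterial for threshold-based
filtering.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from clockmine.datatypes import ProteinSeq, RBHPair, SearchHit

logger = logging.getLogger(__name__)

# Gapped Karlin-Altschul constants for BLOSUM62 with gap open 11 / extend 1.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

_MATRIX_CACHE: dict[str, substitution_matrices.Array] = {}


def load_matrix(name: str = DEFAULT_MATRIX) -> substitution_matrices.Array:
    """Load a substitution matrix, scoring the ambiguity residue X as 0.

    Raises a config error (``ValueError``) for unknown matrix names.
    """
    key = name.upper()
    if key not in _MATRIX_CACHE:
        try:
            matrix = substitution_matrices.load(key)
        except FileNotFoundError as exc:
            raise ValueError(f"unknown substitution matrix {name!r}") from exc
        matrix = matrix.copy()
        if "X" in matrix.alphabet:
            for aa in matrix.alphabet:
                matrix["X", aa] = 0.0
                matrix[aa, "X"] = 0.0
        _MATRIX_CACHE[key] = matrix
    return _MATRIX_CACHE[key]


def _make_aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(matrix_name)
    # A gap of length k costs gap_open + k * gap_extend (BLAST convention).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    a: ProteinSeq | str,
    b: ProteinSeq | str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> tuple[float, int, float]:
    """Optimal local alignment of two protein sequences under affine gaps.

    Returns ``(score, aln_length, percent_similarity)`` where ``aln_length``
    counts alignment columns (including gap columns) and percent similarity
    is the BLAST-style fraction of positive-scoring matched columns over the
    alignment length, in percent. A pair with no positive-scoring residue
    pairing has no local alignment and is reported as ``(0.0, 0, 0.0)``.
    """
    seq_a = a.sequence if isinstance(a, ProteinSeq) else ProteinSeq(id="a", sequence=a).sequence
    seq_b = b.sequence if isinstance(b, ProteinSeq) else ProteinSeq(id="b", sequence=b).sequence
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return 0.0, 0, 0.0
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    subs = aligner.substitution_matrix
    row_a = alignment[0]
    row_b = alignment[1]
    aln_length = len(row_a)
    positives = sum(
        1
        for x, y in zip(row_a, row_b)
        if x != "-" and y != "-" and subs[x, y] > 0
    )
    percent_similarity = 100.0 * positives / aln_length
    return float(score), aln_length, percent_similarity


def estimate_evalue(
    score: float,
    query_len: int,
    db_residues: int,
    lam: float = GAPPED_LAMBDA,
    K: float = GAPPED_K,
) -> float:
    """Karlin-Altschul expectation value ``E = K * m * n * exp(-lambda * S)``.

    Strictly decreasing in the raw score and linear in the database size at
    fixed score.
    """
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query length and database size must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    return K * query_len * db_residues * math.exp(-lam * score)


def bitscore(score: float, lam: float = GAPPED_LAMBDA, K: float = GAPPED_K) -> float:
    """Normalised bit score ``S' = (lambda * S - ln K) / ln 2``."""
    return (lam * score - math.log(K)) / math.log(2)


def _best_first(hits: Iterable[SearchHit]) -> list[SearchHit]:
    return sorted(hits, key=lambda h: h.sort_key)


def forward_search(
    query: ProteinSeq,
    db: Sequence[ProteinSeq],
    max_hits: int = 10000,
    evalue_max: float = 1e-5,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> list[SearchHit]:
    """Search one query against a proteome database.

    Hits with e-value above ``evalue_max`` are dropped; at most ``max_hits``
    are returned, best first (ascending e-value, descending bitscore, then
    subject id — a total, permutation-stable order).
    """
    if not db:
        logger.warning("forward_search: empty database for query %s", query.id)
        return []
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    db_residues = sum(len(s) for s in db)
    m = len(query)
    hits: list[SearchHit] = []
    for subject in db:
        score = aligner.score(query.sequence, subject.sequence)
        if score <= 0:
            continue
        evalue = estimate_evalue(score, m, db_residues)
        if evalue > evalue_max:
            continue
        _, aln_length, percent_similarity = align_pair(
            query, subject, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend
        )
        hits.append(
            SearchHit(
                query_id=query.id,
                subject_id=subject.id,
                subject_organism=subject.organism,
                score=float(score),
                bitscore=bitscore(score),
                evalue=evalue,
                percent_similarity=percent_similarity,
                aln_length=aln_length,
            )
        )
    return _best_first(hits)[:max_hits]


def reciprocal_filter(
    forward_hits: Sequence[SearchHit],
    subject_proteomes: Mapping[str, ProteinSeq],
    query_genome: Sequence[ProteinSeq],
    evalue_max_rev: float = 10.0,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> list[RBHPair]:
    """Accept forward hits whose best reverse hit is the original query.

    Each forward hit's subject is searched back against ``query_genome`` at
    the permissive reverse e-value; the hit is retained only when the
    top-ranked reverse hit (same ordering as :func:`forward_search`) is the
    original query protein. Subjects missing from ``subject_proteomes`` are
    skipped with a logged warning.
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    genome_residues = sum(len(s) for s in query_genome)
    pairs: list[RBHPair] = []
    reverse_cache: dict[str, list[SearchHit]] = {}
    for fwd in forward_hits:
        subject = subject_proteomes.get(fwd.subject_id)
        if subject is None:
            logger.warning(
                "reciprocal_filter: subject %s not retrievable; skipped", fwd.subject_id
            )
            continue
        if fwd.subject_id not in reverse_cache:
            rev_hits = []
            for target in query_genome:
                score = aligner.score(subject.sequence, target.sequence)
                if score <= 0:
                    continue
                evalue = estimate_evalue(score, len(subject), genome_residues)
                if evalue > evalue_max_rev:
                    continue
                rev_hits.append(
                    SearchHit(
                        query_id=subject.id,
                        subject_id=target.id,
                        subject_organism=target.organism,
                        score=float(score),
                        bitscore=bitscore(score),
                        evalue=evalue,
                        percent_similarity=0.0,
                        aln_length=0,
                    )
                )
            reverse_cache[fwd.subject_id] = _best_first(rev_hits)
        rev = reverse_cache[fwd.subject_id]
        if rev and rev[0].subject_id == fwd.query_id:
            pairs.append(
                RBHPair(
                    query_id=fwd.query_id,
                    subject_id=fwd.subject_id,
                    subject_organism=fwd.subject_organism,
                    forward_hit=fwd,
                    reverse_best_id=rev[0].subject_id,
                )
            )
    return pairs


def classify_subtype(
    rbh_pairs: Sequence[RBHPair],
    subtype_of_query: Mapping[str, str] | None = None,
) -> list[RBHPair]:
    """Assign each subject exactly one subtype label.

    A subject can be a reciprocal best hit to several query subtypes (e.g.
    both the KaiC1 and KaiC3 queries). It is labelled by the query with the
    highest forward bitscore; ties break by lowest e-value and then by
    lexicographic query id. Returns one annotated pair per subject.
    ``subtype_of_query`` maps query ids to factor labels (identity default).
    """
    by_subject: dict[str, list[RBHPair]] = defaultdict(list)
    for pair in rbh_pairs:
        by_subject[pair.subject_id].append(pair)
    labelled: list[RBHPair] = []
    for subject_id in sorted(by_subject):
        candidates = by_subject[subject_id]
        winner = min(
            candidates,
            key=lambda p: (-p.forward_hit.bitscore, p.forward_hit.evalue, p.query_id),
        )
        label = winner.query_id
        if subtype_of_query is not None:
            label = subtype_of_query.get(label, label)
        labelled.append(
            RBHPair(
                query_id=winner.query_id,
                subject_id=winner.subject_id,
                subject_organism=winner.subject_organism,
                forward_hit=winner.forward_hit,
                reverse_best_id=winner.reverse_best_id,
                subtype=label,
            )
        )
    return labelled


def rbh_screen(
    queries: Sequence[ProteinSeq],
    proteomes: Mapping[str, Sequence[ProteinSeq]],
    max_hits: int = 10000,
    evalue_max: float = 1e-5,
    evalue_max_rev: float = 10.0,
    subtype_of_query: Mapping[str, str] | None = None,
) -> list[RBHPair]:
    """Run the full forward + reciprocal screen for a query panel.

    ``proteomes`` maps organism name to its protein list. The query panel
    itself serves as the query genome for the reverse search. Returns one
    subtype-labelled pair per accepted subject.
    """
    db: list[ProteinSeq] = [p for prot in proteomes.values() for p in prot]
    subject_lookup = {p.id: p for p in db}
    all_pairs: list[RBHPair] = []
    for query in queries:
        fwd = forward_search(query, db, max_hits=max_hits, evalue_max=evalue_max)
        all_pairs.extend(
            reciprocal_filter(fwd, subject_lookup, list(queries), evalue_max_rev=evalue_max_rev)
        )
    return classify_subtype(all_pairs, subtype_of_query=subtype_of_query)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) import adapter


BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_blast_tabular(path, organism_of_subject: Mapping[str, str] | None = None) -> list[SearchHit]:
    """Import hits from a 12-column BLAST tabular (``outfmt 6``) file.

    ``pident`` is carried into ``percent_similarity`` (real BLAST output does
    not report the positives fraction in this format); raw score is back-
    computed from the bit score.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    hits = []
    for row in table.itertuples(index=False):
        raw = (row.bitscore * math.log(2) + math.log(GAPPED_K)) / GAPPED_LAMBDA
        organism = ""
        if organism_of_subject is not None:
            organism = organism_of_subject.get(row.sseqid, "")
        hits.append(
            SearchHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                subject_organism=organism,
                score=max(raw, 0.0),
                bitscore=float(row.bitscore),
                evalue=float(row.evalue),
                percent_similarity=float(np.clip(row.pident, 0.0, 100.0)),
                aln_length=int(row.length),
            )
        )
    return _best_first(hits)
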