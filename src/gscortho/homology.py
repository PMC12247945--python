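"""Local protein alignment and all-vs-all homology search.

Stands in for the BLASTp step of reciprocal-best-hit ortholog pipelines:
optimal Smith-Waterman local alignment under an affine gap model, an
all-vs-all search with a deterministic tie-break, and an importer for
pre-computed hits in 12-column BLAST tabular (``-outfmt 6``) layout.

Percent identity here follows the Ensembl Compara convention: the number of
identical aligned residues divided by the *full* length of the query
(``query_pid``) or of the target (``target_pid``), not by the alignment
length.  Tabular hit files, which carry alignment-length identity, are
converted on import.  This distinction matters for identity-threshold
ortholog calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AA_ALPHABET",
    "ProteinRecord",
    "AlignmentHit",
    "Scoring",
    "align_local",
    "score_matrix",
    "search_all",
    "import_hits",
    "read_fasta",
    "write_fasta",
    "hits_to_table",
]

#: Residues accepted in protein sequences: the 20 standard amino acids plus
#: the ambiguity code 'X' (which scores 0 against everything).
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence tagged with its species of origin."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains characters outside the "
                f"alphabet: {sorted(bad)}"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a target protein.

    ``query_pid``/``target_pid`` are anchored to the full sequence lengths
    (Ensembl convention); spans are 0-based half-open intervals on the
    unaligned sequences.
    """

    query_id: str
    target_id: str
    score: float
    n_identical: int
    query_pid: float
    target_pid: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix name plus affine gap penalties.

    A gap of length ``g`` costs ``gap_open + g * gap_extend`` (the BLASTp
    convention; defaults are the BLASTp defaults BLOSUM62/11/1).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not self.gap_extend > 0 or self.gap_open < self.gap_extend:
            raise ValueError("require gap_open >= gap_extend > 0")


_MATRIX_CACHE: dict[str, substitution_matrices.Array] = {}


def load_matrix(name: str = "BLOSUM62") -> substitution_matrices.Array:
    """Load a substitution matrix with 'X' forced to score 0 vs everything."""
    if name not in _MATRIX_CACHE:
        mat = substitution_matrices.load(name).copy()
        if "X" in mat.alphabet:
            i = mat.alphabet.index("X")
            mat[i, :] = 0.0
            mat[:, i] = 0.0
        _MATRIX_CACHE[name] = mat
    return _MATRIX_CACHE[name]


def make_aligner(scoring: Scoring = Scoring()) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = load_matrix(scoring.matrix)
    aligner.mode = "local"
    # PairwiseAligner charges open_gap_score for the first gapped residue, so
    # gap_open + gap_extend there reproduces cost(g) = open + g * extend.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _validate(seq: str, role: str) -> None:
    if not seq:
        raise ValueError(f"empty {role} sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{role} sequence has characters outside the alphabet: {sorted(bad)}")


def align_local(
    query: str,
    target: str,
    scoring: Scoring = Scoring(),
    *,
    query_id: str = "query",
    target_id: str = "target",
    _aligner: Align.PairwiseAligner | None = None,
) -> AlignmentHit | None:
    """Optimal local alignment of two proteins; ``None`` if no positive score.

    Smith-Waterman semantics: the returned hit carries the optimal local
    alignment score under the scoring model, the identical-residue count of
    one optimal traceback, and full-length percent identities.
    """
    _validate(query, "query")
    _validate(target, "target")
    aligner = _aligner if _aligner is not None else make_aligner(scoring)
    alignments = aligner.align(query, target)
    if alignments.score <= 0:
        return None
    best = alignments[0]
    counts = best.counts()
    q0, q1 = int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])
    t0, t1 = int(best.aligned[1][0][0]), int(best.aligned[1][-1][1])
    n_ident = int(counts.identities)
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        score=float(alignments.score),
        n_identical=n_ident,
        query_pid=100.0 * n_ident / len(query),
        target_pid=100.0 * n_ident / len(target),
        query_span=(q0, q1),
        target_span=(t0, t1),
    )


def score_matrix(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    scoring: Scoring = Scoring(),
) -> np.ndarray:
    """Matrix of optimal local alignment scores, queries x targets.

    Score-only dynamic programming (no traceback), which is what ranking and
    reciprocity decisions need; full hits are constructed only for winners.
    """
    aligner = make_aligner(scoring)
    qseqs = list(queries.values())
    tseqs = list(targets.values())
    out = np.zeros((len(qseqs), len(tseqs)))
    for i, q in enumerate(qseqs):
        _validate(q, "query")
        for j, t in enumerate(tseqs):
            out[i, j] = aligner.score(q, t)
    return out


def _tie_key(hit: AlignmentHit) -> tuple:
    # Equal scores: prefer higher target_pid, then lexicographic target id.
    return (-hit.score, -hit.target_pid, hit.target_id)


def search_all(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    scoring: Scoring = Scoring(),
    keep_top: int = 1,
    *,
    scores: np.ndarray | None = None,
) -> dict[str, list[AlignmentHit]]:
    """For each query, its ``keep_top`` best-scoring hits across all targets.

    Hits are sorted by score descending with a deterministic tie-break
    (higher target_pid, then lexicographic target id), so the output does
    not depend on input record order.  A precomputed ``scores`` matrix
    (from :func:`score_matrix`) may be supplied to avoid recomputation.
    """
    if not queries or not targets:
        raise ValueError("query and target sets must be non-empty")
    if keep_top < 1:
        raise ValueError("keep_top must be positive")
    if scores is None:
        scores = score_matrix(queries, targets, scoring)
    aligner = make_aligner(scoring)
    tgt_ids = list(targets)
    results: dict[str, list[AlignmentHit]] = {}
    for i, (qid, qseq) in enumerate(queries.items()):
        row = scores[i]
        positive = np.flatnonzero(row > 0)
        if positive.size == 0:
            results[qid] = []
            continue
        # Candidates: everything scoring at least the keep_top-th best score,
        # so score ties at the boundary are resolved by the tie-break rule.
        if positive.size > keep_top:
            cutoff = np.partition(row[positive], positive.size - keep_top)[
                positive.size - keep_top
            ]
        else:
            cutoff = row[positive].min()
        cand = positive[row[positive] >= cutoff]
        hits = []
        for j in sorted(cand, key=lambda j: tgt_ids[j]):
            hit = align_local(
                qseq,
                targets[tgt_ids[j]],
                scoring,
                query_id=qid,
                target_id=tgt_ids[j],
                _aligner=aligner,
            )
            if hit is not None:
                hits.append(hit)
        hits.sort(key=_tie_key)
        results[qid] = hits[:keep_top]
    return results


# ---------------------------------------------------------------------------
# BLAST tabular import / export

_OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def import_hits(
    path: str | Path,
    query_lengths: Mapping[str, int],
    target_lengths: Mapping[str, int],
) -> list[AlignmentHit]:
    """Read hits from a 12-column BLAST tabular file.

    Alignment-length percent identity (``pident``) is converted to
    full-length query/target percent identity via the stored sequence
    lengths; 1-based inclusive coordinates become 0-based half-open.
    Rows are returned in file order.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                qid, tid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if qid not in query_lengths:
                raise KeyError(f"{path}:{lineno}: unknown query sequence id {qid!r}")
            if tid not in target_lengths:
                raise KeyError(f"{path}:{lineno}: unknown target sequence id {tid!r}")
            n_ident = int(round(pident * length / 100.0))
            if sstart > send:  # minus-orientation input; normalize
                sstart, send = send, sstart
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    target_id=tid,
                    score=bitscore,
                    n_identical=n_ident,
                    query_pid=100.0 * n_ident / query_lengths[qid],
                    target_pid=100.0 * n_ident / target_lengths[tid],
                    query_span=(qstart - 1, qend),
                    target_span=(sstart - 1, send),
                )
            )
    return hits


def hits_to_table(hits: Iterable[AlignmentHit]):
    """Hits as a pandas DataFrame in BLAST-tabular-like column order."""
    import pandas as pd

    rows = [
        {
            "qseqid": h.query_id,
            "sseqid": h.target_id,
            "score": h.score,
            "n_identical": h.n_identical,
            "query_pid": h.query_pid,
            "target_pid": h.target_pid,
            "qstart": h.query_span[0],
            "qend": h.query_span[1],
            "sstart": h.target_span[0],
            "send": h.target_span[1],
        }
        for h in hits
    ]
    return pd.DataFrame(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file as an id -> sequence mapping (insertion-ordered)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
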