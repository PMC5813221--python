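"""Local pairwise alignment, percent identity, and empirical E-value calibration.

Alignment is exact affine-gap dynamic programming (Smith-Waterman for local
mode; for the window scan, a "glocal" mode that aligns the whole query window
while leaving subject end overhangs unpenalized).  The heavy lifting is done
by Biopython's :class:`Bio.Align.PairwiseAligner` C engine behind a thin,
typed surface.

Gap cost convention: a gap of length ``g`` costs ``gap_open + (g-1) *
gap_extend``.  Defaults are BLOSUM50 with gap_open −10 and gap_extend −2, the
classic FASTA protein defaults.

E-values are calibrated empirically: the query is scored against
residue-shuffled database entries and the score distribution is fitted by
maximum likelihood to a Gumbel (type-I extreme-value) distribution, the
asymptotic law for optimal local alignment scores.  ``E(S) = D · P(score ≥ S)``
with ``D`` the number of database entries, so E is the expected number of
chance hits at or above a score, and doubling the database doubles E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from Bio import Align
from Bio.Align import substitution_matrices

from .records import AMBIGUITY_CODES, AllergenEntry, ProteinRecord

GAP = "-"


def _load_matrix(name_or_path: str):
    """Load a substitution matrix by name or from an NCBI-format text file."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        pass
    path = Path(name_or_path)
    if path.exists():
        with open(path) as handle:
            return substitution_matrices.read(handle)
    raise ValueError(f"unknown substitution matrix {name_or_path!r}")


@lru_cache(maxsize=8)
def _extended_matrix(name_or_path: str):
    """Matrix extended with zero-scoring rows for ambiguity codes it lacks.

    BLOSUM matrices ship B/Z/X rows but not U (selenocysteine); undefined
    ambiguity pairings score 0 by contract.
    """
    m = _load_matrix(name_or_path)
    missing = "".join(sorted(set("XBZU") - set(m.alphabet)))
    if not missing:
        return m
    alphabet = m.alphabet + missing
    big = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in m.alphabet:
        for b in m.alphabet:
            big[a, b] = m[a, b]
    return big


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``matrix_name`` may be a built-in name (e.g. ``"BLOSUM50"``) or a path to
    an NCBI-format matrix file.  Invariant: ``gap_open <= gap_extend < 0``.
    """

    matrix_name: str = "BLOSUM50"
    gap_open: int = -10
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError(
                f"require gap_open <= gap_extend < 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )

    @property
    def matrix(self):
        return _extended_matrix(self.matrix_name)

    def score_pair(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def _aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = float(self.gap_open)
        aligner.extend_gap_score = float(self.gap_extend)
        if mode == "local":
            aligner.mode = "local"
        elif mode == "glocal":
            # Global in the (window) query, free end gaps in the subject.
            aligner.mode = "global"
            aligner.end_insertion_score = 0.0
        else:
            raise ValueError(f"unknown alignment mode {mode!r}")
        return aligner

    def local_aligner(self) -> Align.PairwiseAligner:
        return self._aligner("local")

    def glocal_aligner(self) -> Align.PairwiseAligner:
        return self._aligner("glocal")


@dataclass
class AlignmentResult:
    """A scored pairwise alignment with identity bookkeeping.

    Spans are 1-based inclusive intervals on the parent sequences; empty
    alignments (no positive-scoring local path) have ``aligned_columns = 0``
    and no spans.  ``identities`` counts aligned columns with identical
    non-ambiguous residues; gap columns sit in the percent-identity
    denominator (FASTA-style "identity over alignment length").
    """

    query_id: str
    subject_id: str
    raw_score: int
    query_span: tuple[int, int] | None
    subject_span: tuple[int, int] | None
    aligned_columns: int
    identities: int
    query_length: int = 0
    subject_length: int = 0
    evalue: float | None = None

    @property
    def is_empty(self) -> bool:
        return self.aligned_columns == 0

    @property
    def percent_identity(self) -> float:
        if self.is_empty:
            return 0.0
        return 100.0 * self.identities / self.aligned_columns


def percent_identity(aln: AlignmentResult) -> float:
    """Percent identity over alignment length; raises on empty alignments."""
    if aln.is_empty:
        raise ValueError(
            f"alignment {aln.query_id} vs {aln.subject_id} is empty; "
            "percent identity undefined"
        )
    return aln.percent_identity


def _column_stats(row_q: str, row_s: str) -> tuple[int, int]:
    """(aligned_columns, identities) over two gapped alignment rows."""
    columns = 0
    identities = 0
    for a, b in zip(row_q, row_s):
        columns += 1
        if a == b and a != GAP and a not in AMBIGUITY_CODES:
            identities += 1
    return columns, identities


def _seq_of(x: ProteinRecord | AllergenEntry | str) -> str:
    if isinstance(x, str):
        return x
    if isinstance(x, AllergenEntry):
        return x.record.sequence
    return x.sequence


def _id_of(x: ProteinRecord | AllergenEntry | str) -> str:
    if isinstance(x, str):
        return "<anonymous>"
    return x.id


def local_align(query, subject, scheme: ScoringScheme) -> AlignmentResult:
    """Optimal Smith-Waterman affine-gap local alignment.

    Returns an empty result (raw_score 0) when no alignment scores above
    zero, e.g. for sequences over disjoint, negatively-scoring alphabets.
    """
    q, s = _seq_of(query), _seq_of(subject)
    if len(q) < 1 or len(s) < 1:
        raise ValueError("local_align: sequences must have length >= 1")
    aligner = scheme.local_aligner()
    score = aligner.score(q, s)
    if score <= 0:
        return AlignmentResult(
            query_id=_id_of(query), subject_id=_id_of(subject), raw_score=0,
            query_span=None, subject_span=None, aligned_columns=0, identities=0,
            query_length=len(q), subject_length=len(s),
        )
    aln = aligner.align(q, s)[0]
    row_q, row_s = str(aln[0]), str(aln[1])
    columns, identities = _column_stats(row_q, row_s)
    coords = aln.coordinates
    q_start, q_end = int(coords[0][0]), int(coords[0][-1])
    s_start, s_end = int(coords[1][0]), int(coords[1][-1])
    return AlignmentResult(
        query_id=_id_of(query), subject_id=_id_of(subject),
        raw_score=int(round(score)),
        query_span=(q_start + 1, q_end), subject_span=(s_start + 1, s_end),
        aligned_columns=columns, identities=identities,
        query_length=len(q), subject_length=len(s),
    )


def glocal_align(query, subject, scheme: ScoringScheme) -> AlignmentResult:
    """Align all of ``query`` against ``subject`` with free subject end gaps.

    Used by the sliding-window scan: the whole 80-mer window must be aligned,
    so its identity denominator is the window plus any internal gaps, never a
    trimmed high-scoring core.  The raw score may be negative.
    """
    q, s = _seq_of(query), _seq_of(subject)
    if len(q) < 1 or len(s) < 1:
        raise ValueError("glocal_align: sequences must have length >= 1")
    aligner = scheme.glocal_aligner()
    aln = aligner.align(q, s)[0]
    row_q, row_s = str(aln[0]), str(aln[1])
    # Trim the unpenalized subject overhangs (leading/trailing query gaps).
    start = 0
    end = len(row_q)
    while start < end and row_q[start] == GAP:
        start += 1
    while end > start and row_q[end - 1] == GAP:
        end -= 1
    core_q, core_s = row_q[start:end], row_s[start:end]
    columns, identities = _column_stats(core_q, core_s)
    s_prefix = start - row_s[:start].count(GAP)
    s_len_core = len(core_s) - core_s.count(GAP)
    q_len_core = len(core_q) - core_q.count(GAP)
    return AlignmentResult(
        query_id=_id_of(query), subject_id=_id_of(subject),
        raw_score=int(round(aln.score)),
        query_span=(1, q_len_core),
        subject_span=(s_prefix + 1, s_prefix + s_len_core) if s_len_core else None,
        aligned_columns=columns, identities=identities,
        query_length=len(q), subject_length=len(s),
    )


@lru_cache(maxsize=8)
def _matrix_arrays(matrix_name: str):
    """(char -> index map, dense score ndarray) for fast ungapped scoring."""
    m = _extended_matrix(matrix_name)
    index = {c: i for i, c in enumerate(m.alphabet)}
    return index, np.asarray(m, dtype=float)


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    return np.fromiter((index[c] for c in seq), dtype=np.intp, count=len(seq))


def window_align(window, subject, scheme: ScoringScheme) -> AlignmentResult:
    """Best ungapped placement of a query window on a subject.

    The window slides over the subject at every offset (overhangs allowed and
    unpenalized); the placement with the highest substitution-matrix score is
    reported, ties broken toward the smallest subject offset.  Identity is
    counted positionally over the whole window, so a segment planted with k
    substitutions scores exactly ``100·(W−k)/W`` — the arithmetic the
    >35 %-over-80-AA criterion is defined on.  Indels are the province of the
    full-length scan, not the window scan.
    """
    w, s = _seq_of(window), _seq_of(subject)
    if len(w) < 1 or len(s) < 1:
        raise ValueError("window_align: sequences must have length >= 1")
    index, matrix = _matrix_arrays(scheme.matrix_name)
    wc, sc = _encode(w, index), _encode(s, index)
    W, L = len(wc), len(sc)
    S = matrix[wc[:, None], sc[None, :]]
    ambiguous = np.isin(wc, _encode("".join(sorted(AMBIGUITY_CODES)), index))
    ident = (wc[:, None] == sc[None, :]) & ~ambiguous[:, None]
    # diagonal sums: position k corresponds to subject offset k-(W-1)
    scores = np.zeros(W + L - 1)
    idents = np.zeros(W + L - 1, dtype=int)
    for i in range(W):
        lo = W - 1 - i
        scores[lo:lo + L] += S[i]
        idents[lo:lo + L] += ident[i]
    k = int(np.argmax(scores))  # np.argmax takes the first (smallest offset)
    offset = k - (W - 1)        # subject position aligned to window[0]
    overlap_start = max(0, offset)
    overlap_end = min(L, offset + W)
    return AlignmentResult(
        query_id=_id_of(window), subject_id=_id_of(subject),
        raw_score=int(round(scores[k])),
        query_span=(1, W),
        subject_span=(overlap_start + 1, overlap_end),
        aligned_columns=W,
        identities=int(idents[k]),
        query_length=W, subject_length=L,
    )


@dataclass
class EvdCalibration:
    """Gumbel fit to query-vs-shuffled-database alignment scores.

    ``loc``/``scale`` are the fitted Gumbel location and scale (so the
    Karlin-Altschul-style decay rate is ``lambda = 1/scale``); ``db_size`` is
    the number of database entries the calibration extrapolates over and
    ``db_residues`` their total residue count.
    """

    loc: float
    scale: float
    n_shuffles: int
    db_size: int
    db_residues: int
    seed: int
    mode: str = "local"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("fitted EVD scale must be positive")

    @property
    def lambda_(self) -> float:
        return 1.0 / self.scale

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "EvdCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


def _shuffled_scores(query, db: Sequence, scheme: ScoringScheme,
                     n_shuffles: int, rng: np.random.Generator,
                     mode: str) -> np.ndarray:
    if mode == "window":
        def scorer(q, s):
            return window_align(q, s, scheme).raw_score
    else:
        aligner = (scheme.local_aligner() if mode == "local"
                   else scheme.glocal_aligner())
        scorer = aligner.score
    q = _seq_of(query)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        entry_seq = _seq_of(db[i % len(db)])
        shuffled = "".join(
            rng.permutation(np.frombuffer(entry_seq.encode(), dtype="S1"))
            .astype(str)
        )
        scores[i] = scorer(q, shuffled)
    return scores


def calibrate_evalues(query, db: Sequence, scheme: ScoringScheme,
                      n_shuffles: int = 500, seed: int = 0,
                      mode: str = "local") -> EvdCalibration:
    """Fit the null score distribution from residue-shuffled database entries.

    Database entries are cycled; each is residue-shuffled independently and
    scored against the query.  The scores are fitted by maximum likelihood to
    a Gumbel distribution.  Reproducible under a fixed seed.
    """
    if n_shuffles < 100:
        raise ValueError("calibrate_evalues: need n_shuffles >= 100")
    if len(db) < 5:
        raise ValueError(
            f"calibrate_evalues: database of {len(db)} entries is too small "
            "to fit a null distribution (need >= 5)"
        )
    rng = np.random.default_rng(seed)
    scores = _shuffled_scores(query, db, scheme, n_shuffles, rng, mode)
    loc, scale = stats.gumbel_r.fit(scores)
    return EvdCalibration(
        loc=float(loc), scale=float(scale), n_shuffles=n_shuffles,
        db_size=len(db),
        db_residues=sum(len(_seq_of(e)) for e in db),
        seed=seed, mode=mode,
    )


def evalue(score: float, cal: EvdCalibration,
           db_size: int | None = None) -> float:
    """Expected number of chance hits scoring >= ``score``.

    Linear in database size; strictly decreasing in score.
    """
    if cal is None:
        raise ValueError("evalue: calibration required")
    d = cal.db_size if db_size is None else db_size
    return float(d * stats.gumbel_r.sf(score, loc=cal.loc, scale=cal.scale))
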