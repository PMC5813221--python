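"""The three search modalities of the CODEX-style screen.

* ``full_scan`` — one best local alignment per database entry, counted at
  E < 10 and E < 1.0, plus the Aalberse full-length > 50 % identity count.
* ``window_scan`` — every 80-residue query window aligned to every entry; a
  window passes for an entry when its identity is strictly > 35 % and its
  E-value is < 10.
* ``word_scan`` — exact 8-mer word search against a prebuilt index.

``screen`` combines the three into a per-query report row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .align import (
    AlignmentResult,
    EvdCalibration,
    ScoringScheme,
    calibrate_evalues,
    evalue,
    local_align,
    window_align,
)
from .records import AllergenEntry, ProteinRecord

logger = logging.getLogger(__name__)

WINDOW_WIDTH = 80
WORD_SIZE = 8
WINDOW_ID_THRESHOLD = 35.0  # strict: a window passes only when identity > 35 %
FULL_LENGTH_ID_THRESHOLD = 50.0
E_REPORT = 10.0
E_STRONG = 1.0


def full_length_identity(aln: AlignmentResult) -> float:
    """Identity of the best local alignment spread over the full length.

    ``100 · identities / max(len(query), len(subject))`` — the currency of
    the Aalberse > 50 % full-length rule and of safe-homolog context ranking.
    """
    denom = max(aln.query_length, aln.subject_length)
    if denom == 0:
        raise ValueError("alignment carries no sequence lengths")
    return 100.0 * aln.identities / denom


@dataclass
class FullScanSummary:
    """Per-query result of the full-length scan (Table-2 "Full FASTA" block)."""

    query_id: str
    hits: list[AlignmentResult]          # sorted ascending by E
    n_e10: int
    n_e1: int
    n_id50: int
    id50_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_e1 <= self.n_e10, "count nesting violated"


def full_scan(query: ProteinRecord, db: Sequence[AllergenEntry],
              scheme: ScoringScheme, cal: EvdCalibration,
              thresholds: tuple[float, float] = (E_REPORT, E_STRONG),
              evalue_db_size: int | None = None) -> FullScanSummary:
    """Best local alignment of the query against every database entry.

    ``evalue_db_size`` pins the database size used in the E-value
    extrapolation (default: the size of ``db``); pinning it keeps the
    statistical context fixed when comparing scans of nested databases.
    """
    if not db:
        raise ValueError("full_scan: empty database")
    e_report, e_strong = max(thresholds), min(thresholds)
    d = len(db) if evalue_db_size is None else evalue_db_size
    hits = []
    for entry in db:
        aln = local_align(query, entry, scheme)
        aln.evalue = evalue(aln.raw_score, cal, db_size=d)
        hits.append((aln, entry))
    hits.sort(key=lambda pair: (pair[0].evalue, pair[0].subject_id))
    n_e10 = sum(1 for aln, _ in hits if aln.evalue < e_report)
    n_e1 = sum(1 for aln, _ in hits if aln.evalue < e_strong)
    id50 = [
        entry.display_name
        for aln, entry in hits
        if aln.evalue < e_report
        and full_length_identity(aln) > FULL_LENGTH_ID_THRESHOLD
    ]
    return FullScanSummary(
        query_id=query.id,
        hits=[aln for aln, _ in hits],
        n_e10=n_e10, n_e1=n_e1, n_id50=len(id50), id50_subjects=id50,
    )


def enumerate_windows(query: ProteinRecord | str, width: int = WINDOW_WIDTH,
                      step: int = 1) -> list[tuple[int, str]]:
    """All sliding windows as (1-based start, subsequence) pairs.

    A query shorter than ``width`` yields a single full-length window.
    """
    seq = query if isinstance(query, str) else query.sequence
    if len(seq) < 1:
        raise ValueError("enumerate_windows: empty sequence")
    if len(seq) <= width:
        return [(1, seq)]
    return [(i + 1, seq[i:i + width])
            for i in range(0, len(seq) - width + 1, step)]


@dataclass
class WindowHit:
    """Best alignment of one query window to one database entry."""

    window_start: int
    window_length: int
    subject_id: str
    identity: float
    evalue: float

    @property
    def passes(self) -> bool:
        return self.identity > WINDOW_ID_THRESHOLD and self.evalue < E_REPORT


@dataclass
class WindowAllergenStats:
    subject_id: str
    display_name: str
    pass_count: int = 0
    best_identity: float = 0.0
    best_window_start: int | None = None


@dataclass
class WindowScanSummary:
    """Per-query result of the sliding 80-mer scan (Table-2 "80 mer" block)."""

    query_id: str
    n_windows: int
    per_allergen: dict[str, WindowAllergenStats]

    @property
    def best_subject_id(self) -> str | None:
        passing = [s for s in self.per_allergen.values() if s.pass_count > 0]
        if not passing:
            return None
        return max(passing, key=lambda s: (s.best_identity, s.subject_id)).subject_id

    @property
    def total_passes(self) -> int:
        return sum(s.pass_count for s in self.per_allergen.values())


def calibrate_window_scan(query: ProteinRecord, db: Sequence[AllergenEntry],
                          scheme: ScoringScheme, n_shuffles: int = 200,
                          seed: int = 0) -> EvdCalibration:
    """Null-score calibration for the window scan.

    One glocal calibration from a representative window (the first) is reused
    for every window of the query; the identity > 35 % rule, not the loose
    E < 10 gate, is the binding criterion of the window scan.
    """
    window = enumerate_windows(query)[0][1]
    return calibrate_evalues(window, db, scheme, n_shuffles=n_shuffles,
                             seed=seed, mode="window")


def window_scan(query: ProteinRecord, db: Sequence[AllergenEntry],
                scheme: ScoringScheme, cal: EvdCalibration,
                width: int = WINDOW_WIDTH) -> WindowScanSummary:
    """Slide every query window over every entry; count windows passing
    identity > 35 % (strict) at E < 10.

    Window placement is exact and ungapped (see
    :func:`allerscreen.align.window_align`): identity is positional over the
    full window, which is what the >35 %-over-80-AA criterion's arithmetic
    (e.g. 29/80 passing, 28/80 not) presumes.
    """
    if not db:
        raise ValueError("window_scan: empty database")
    windows = enumerate_windows(query, width)
    per: dict[str, WindowAllergenStats] = {
        e.record.id: WindowAllergenStats(e.record.id, e.display_name)
        for e in db
    }
    for start, wseq in windows:
        for entry in db:
            aln = window_align(wseq, entry, scheme)
            e = evalue(aln.raw_score, cal, db_size=len(db))
            hit = WindowHit(
                window_start=start, window_length=len(wseq),
                subject_id=entry.record.id,
                identity=aln.percent_identity, evalue=e,
            )
            stats = per[entry.record.id]
            if hit.identity > stats.best_identity:
                stats.best_identity = hit.identity
                stats.best_window_start = start
            if hit.passes:
                stats.pass_count += 1
    return WindowScanSummary(query_id=query.id, n_windows=len(windows),
                             per_allergen=per)


@dataclass
class WordIndex:
    """Exact k-mer lookup: word -> list of (entry id, 0-based offset)."""

    k: int
    words: dict[str, list[tuple[str, int]]]
    entry_ids: list[str]
    display_names: dict[str, str]

    def __contains__(self, word: str) -> bool:
        return word in self.words


def build_word_index(db: Sequence[AllergenEntry], k: int = WORD_SIZE) -> WordIndex:
    """Index every k-mer of every entry; entries shorter than k contribute
    nothing."""
    if k < 1:
        raise ValueError("build_word_index: k must be >= 1")
    words: dict[str, list[tuple[str, int]]] = {}
    for entry in db:
        seq = entry.record.sequence
        for off in range(len(seq) - k + 1):
            words.setdefault(seq[off:off + k], []).append((entry.record.id, off))
    return WordIndex(
        k=k, words=words,
        entry_ids=[e.record.id for e in db],
        display_names={e.record.id: e.display_name for e in db},
    )


@dataclass
class WordMatch:
    word: str
    query_offsets: list[int]
    subject_offsets: list[int]


@dataclass
class WordScanSummary:
    """Per-query result of the exact 8-mer search (Table-2 "8 mer" block)."""

    query_id: str
    k: int
    per_allergen: dict[str, int]                 # distinct shared k-mers
    matches: dict[str, list[WordMatch]] = field(default_factory=dict)

    @property
    def total_hits(self) -> int:
        return sum(self.per_allergen.values())


def word_scan(query: ProteinRecord, index: WordIndex) -> WordScanSummary:
    """Count distinct query k-mers found exactly in each database entry."""
    k = index.k
    counts = {eid: 0 for eid in index.entry_ids}
    matches: dict[str, list[WordMatch]] = {}
    seq = query.sequence
    if len(seq) < k:
        logger.warning(
            "query %s is shorter than the word size %d; zero counts",
            query.id, k,
        )
        return WordScanSummary(query_id=query.id, k=k, per_allergen=counts)
    query_words: dict[str, list[int]] = {}
    for off in range(len(seq) - k + 1):
        query_words.setdefault(seq[off:off + k], []).append(off)
    for word, q_offsets in query_words.items():
        hits = index.words.get(word)
        if not hits:
            continue
        per_entry: dict[str, list[int]] = {}
        for eid, s_off in hits:
            per_entry.setdefault(eid, []).append(s_off)
        for eid, s_offsets in per_entry.items():
            counts[eid] += 1
            matches.setdefault(eid, []).append(
                WordMatch(word=word, query_offsets=q_offsets,
                          subject_offsets=s_offsets)
            )
    return WordScanSummary(query_id=query.id, k=k, per_allergen=counts,
                           matches=matches)


def screen(query: ProteinRecord, db: Sequence[AllergenEntry],
           scheme: ScoringScheme, cal: EvdCalibration,
           cal_window: EvdCalibration | None = None,
           word_index: WordIndex | None = None,
           safe_set: Sequence[ProteinRecord] | None = None):
    """Run all three scans for one query and assemble a report row.

    ``cal`` is the full-length (local-mode) calibration; ``cal_window`` the
    glocal window calibration (derived from ``cal.seed`` when omitted).
    Returns a :class:`allerscreen.report.ScreenReport`.
    """
    from .report import build_report  # deferred: report imports this module

    if cal_window is None:
        cal_window = calibrate_window_scan(query, db, scheme, seed=cal.seed)
    if word_index is None:
        word_index = build_word_index(db)
    full = full_scan(query, db, scheme, cal)
    windows = window_scan(query, db, scheme, cal_window)
    words = word_scan(query, word_index)
    return build_report(query, db, full, windows, words, scheme, cal,
                        safe_set=safe_set)
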