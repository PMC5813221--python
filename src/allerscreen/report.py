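"""Table-2-style reporting, verdict flags, and end-to-end orchestration.

The screen's per-query output mirrors the summary table of a CODEX-style
assessment: full-length hit counts at E < 10 and E < 1.0, the Aalberse
full-length > 50 % identity count with matched allergen names, per-allergen
80-mer window pass counts and best identities, per-allergen 8-mer counts, and
three verdict flags.  Counts above a display cap print as "20+" in the TSV
(only the E < 10 column, matching convention) while the JSON mirror always
keeps exact integers.

The overall verdict is deliberately tri-state — "no significant match",
"match — context outranked by safe homologs", "match — review required" —
and never auto-claims allergenicity: sequence screening is a flagging step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .align import EvdCalibration, ScoringScheme, calibrate_evalues
from .phylo import (
    ContextVerdict,
    context_rank,
    nj_tree,
    pairwise_identity_matrix,
)
from .records import (
    AllergenEntry,
    ProteinRecord,
    load_database,
    read_fasta,
)
from .screen import (
    FullScanSummary,
    WindowScanSummary,
    WordScanSummary,
    build_word_index,
    calibrate_window_scan,
    full_scan,
    window_scan,
    word_scan,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_CALIBRATION_ERROR = 3
EXIT_INTERNAL_ERROR = 4

LABEL_NO_MATCH = "no significant match"
LABEL_OUTRANKED = "match — context outranked by safe homologs"
LABEL_REVIEW = "match — review required"


class PipelineInputError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


class InternalInconsistencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All tunables of one screening run.  The seed is mandatory."""

    seed: int
    matrix_name: str = "BLOSUM50"
    gap_open: int = -10
    gap_extend: int = -2
    e_thresholds: tuple[float, float] = (10.0, 1.0)
    window_width: int = 80
    word_size: int = 8
    n_shuffles: int = 500
    display_cap: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("RunConfig: seed is mandatory")
        if min(self.e_thresholds) <= 0:
            raise ValueError("E thresholds must be positive")
        if self.window_width < self.word_size:
            raise ValueError("window width must be >= word size")

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(matrix_name=self.matrix_name,
                             gap_open=self.gap_open,
                             gap_extend=self.gap_extend)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "e_thresholds" in raw:
            raw["e_thresholds"] = tuple(raw["e_thresholds"])
        return cls(**raw)


@dataclass
class AllergenRow:
    """One matched-allergen line under a query (Table-2 style)."""

    subject_id: str
    display_name: str
    window_passes: int
    best_window_identity: float
    word_hits: int


@dataclass
class ScreenReport:
    """Per-query aggregate of the three scans plus verdicts and metadata."""

    query_id: str
    n_aa: int
    n_e10: int
    n_e1: int
    n_id50: int
    id50_allergens: list[str]
    allergen_rows: list[AllergenRow]
    flags: dict[str, bool]
    label: str
    context: ContextVerdict | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_e1 > self.n_e10:
            raise InternalInconsistencyError(
                f"{self.query_id}: n_e1 ({self.n_e1}) exceeds n_e10 "
                f"({self.n_e10})"
            )


def derive_flags(full: FullScanSummary, windows: WindowScanSummary,
                 words: WordScanSummary) -> dict[str, bool]:
    return {
        "fulllength_gt50": full.n_id50 >= 1,
        "window_gt35": any(s.pass_count >= 1
                           for s in windows.per_allergen.values()),
        "word8_hit": any(c >= 1 for c in words.per_allergen.values()),
    }


def verdict(report: ScreenReport) -> tuple[dict[str, bool], str]:
    """Recompute the flag set and overall label from a report row.

    Pure and idempotent: depends only on the stored summaries.
    """
    flags = dict(report.flags)
    if not any(flags.values()):
        label = LABEL_NO_MATCH
    elif report.context is not None and report.context.outranked:
        label = LABEL_OUTRANKED
    else:
        label = LABEL_REVIEW
    return flags, label


def build_report(query: ProteinRecord, db: Sequence[AllergenEntry],
                 full: FullScanSummary, windows: WindowScanSummary,
                 words: WordScanSummary, scheme: ScoringScheme,
                 cal: EvdCalibration,
                 safe_set: Sequence[ProteinRecord] | None = None,
                 ) -> ScreenReport:
    """Assemble one report row from the three scan summaries."""
    flags = derive_flags(full, windows, words)
    names = {e.record.id: e.display_name for e in db}
    matched_ids = sorted(
        {eid for eid, s in windows.per_allergen.items() if s.pass_count > 0}
        | {eid for eid, c in words.per_allergen.items() if c > 0},
    )
    rows = [
        AllergenRow(
            subject_id=eid,
            display_name=names.get(eid, eid),
            window_passes=windows.per_allergen[eid].pass_count,
            best_window_identity=windows.per_allergen[eid].best_identity,
            word_hits=words.per_allergen.get(eid, 0),
        )
        for eid in matched_ids
    ]
    rows.sort(key=lambda r: (-r.best_window_identity, r.subject_id))

    context = None
    if safe_set is not None:
        context = context_rank(query, full, safe_set, scheme)

    report = ScreenReport(
        query_id=query.id, n_aa=query.length,
        n_e10=full.n_e10, n_e1=full.n_e1,
        n_id50=full.n_id50, id50_allergens=list(full.id50_subjects),
        allergen_rows=rows, flags=flags, label="",
        context=context,
        metadata={
            "matrix": scheme.matrix_name,
            "gap_open": scheme.gap_open,
            "gap_extend": scheme.gap_extend,
            "calibration_seed": cal.seed,
            "n_shuffles": cal.n_shuffles,
            "db_size": cal.db_size,
        },
    )
    _, report.label = verdict(report)
    return report


def _capped(value: int, cap: int) -> str:
    return f"{cap}+" if value > cap else str(value)


TSV_COLUMNS = [
    "query_id", "n_aa", "fasta_e10", "fasta_e1", "id50_count",
    "id50_allergens", "allergen", "win_hits_gt35", "best_window_id_pct",
    "word8_hits", "verdict",
]


def render_table(reports: Sequence[ScreenReport], cap: int = 20) -> str:
    """Render reports as a TSV table, one line per (query, matched allergen).

    Queries with no matched allergen get a single line with empty allergen
    cells (empty = not applicable; 0 = scanned and found nothing).  Only the
    E < 10 column is display-capped ("20+"); the JSON mirror keeps exact
    integers for every count.
    """
    lines = ["\t".join(TSV_COLUMNS)]
    for rep in reports:
        base = [
            rep.query_id, str(rep.n_aa), _capped(rep.n_e10, cap),
            str(rep.n_e1), str(rep.n_id50),
            ",".join(rep.id50_allergens),
        ]
        if not rep.allergen_rows:
            lines.append("\t".join(base + ["", "", "", "", rep.label]))
            continue
        for i, row in enumerate(rep.allergen_rows):
            prefix = base if i == 0 else base[:1] + [""] * 5
            lines.append("\t".join(prefix + [
                row.display_name,
                str(row.window_passes),
                f"{row.best_window_identity:.1f}",
                str(row.word_hits),
                rep.label if i == 0 else "",
            ]))
    return "\n".join(lines) + "\n"


def _context_dict(c: ContextVerdict | None) -> dict | None:
    if c is None:
        return None
    return {
        "query_id": c.query_id, "status": c.status,
        "allergen_id": c.allergen_id, "allergen_identity": c.allergen_identity,
        "safe_id": c.safe_id, "safe_identity": c.safe_identity,
        "outranked": c.outranked,
    }


def reports_to_json(reports: Sequence[ScreenReport],
                    run_metadata: dict | None = None) -> str:
    """Lossless JSON mirror of the report table (exact counts, no caps)."""
    payload = {
        "run": run_metadata or {},
        "queries": [
            {
                "query_id": r.query_id,
                "n_aa": r.n_aa,
                "n_e10": r.n_e10,
                "n_e1": r.n_e1,
                "n_id50": r.n_id50,
                "id50_allergens": r.id50_allergens,
                "allergens": [
                    {
                        "subject_id": a.subject_id,
                        "name": a.display_name,
                        "window_passes": a.window_passes,
                        "best_window_identity": a.best_window_identity,
                        "word_hits": a.word_hits,
                    }
                    for a in r.allergen_rows
                ],
                "flags": r.flags,
                "label": r.label,
                "context": _context_dict(r.context),
                "metadata": r.metadata,
            }
            for r in reports
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def database_fingerprint(db: Sequence[AllergenEntry]) -> str:
    h = hashlib.sha256()
    for e in db:
        h.update(e.record.id.encode())
        h.update(b"\x00")
        h.update(e.record.sequence.encode())
        h.update(b"\x01")
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, query_path: str | Path,
                 db_fasta: str | Path, db_meta: str | Path,
                 safe_path: str | Path | None = None,
                 out_dir: str | Path = ".") -> dict[str, Path]:
    """Deterministic end-to-end run: load, calibrate, screen, write outputs.

    Writes ``report.tsv``, ``report.json`` and, when a safe set is supplied,
    one Newick tree per flagged query under ``trees/``.  Logs go to standard
    error; results go only to files.
    """
    t0 = time.monotonic()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        queries = read_fasta(query_path)
        db = load_database(db_fasta, db_meta)
        safe_set = read_fasta(safe_path) if safe_path else None
    except (OSError, ValueError) as exc:
        raise PipelineInputError(f"input stage: {exc}") from exc
    if not queries:
        raise PipelineInputError(f"input stage: no query sequences in {query_path}")
    if not db:
        raise PipelineInputError(f"input stage: empty database {db_fasta}")

    scheme = config.scheme
    fingerprint = database_fingerprint(db)
    logger.info("loaded %d queries, %d database entries (fingerprint %s)",
                len(queries), len(db), fingerprint)
    word_index = build_word_index(db, k=config.word_size)

    reports = []
    stage_times = {}
    for i, query in enumerate(queries):
        # per-query seeds derived deterministically from the run seed
        qseed = (config.seed + 7919 * i) % (2 ** 31)
        t1 = time.monotonic()
        try:
            cal = calibrate_evalues(query, db, scheme,
                                    n_shuffles=config.n_shuffles, seed=qseed)
            cal_window = calibrate_window_scan(query, db, scheme, seed=qseed)
        except ValueError as exc:
            raise CalibrationError(f"calibration stage ({query.id}): {exc}") from exc
        full = full_scan(query, db, scheme, cal,
                         thresholds=config.e_thresholds)
        windows = window_scan(query, db, scheme, cal_window,
                              width=config.window_width)
        words = word_scan(query, word_index)
        report = build_report(query, db, full, windows, words, scheme, cal,
                              safe_set=safe_set)
        report.metadata["db_fingerprint"] = fingerprint
        reports.append(report)
        stage_times[query.id] = round(time.monotonic() - t1, 3)
        logger.info("screened %s in %.2fs: %s", query.id,
                    stage_times[query.id], report.label)

        if safe_set and any(report.flags.values()):
            tree_records = _context_tree_records(query, db, full, safe_set)
            if len(tree_records) >= 3:
                dm = pairwise_identity_matrix(tree_records, scheme)
                tree = nj_tree(dm)
                trees_dir = out / "trees"
                trees_dir.mkdir(exist_ok=True)
                tree.write(trees_dir / f"{_safe_name(query.id)}.nwk")

    tsv_path = out / "report.tsv"
    json_path = out / "report.json"
    tsv_path.write_text(render_table(reports, cap=config.display_cap))
    run_meta = {
        "matrix": config.matrix_name,
        "gap_open": config.gap_open,
        "gap_extend": config.gap_extend,
        "e_thresholds": list(config.e_thresholds),
        "window_width": config.window_width,
        "word_size": config.word_size,
        "n_shuffles": config.n_shuffles,
        "seed": config.seed,
        "db_fingerprint": fingerprint,
        "n_queries": len(queries),
        "n_db_entries": len(db),
    }
    json_path.write_text(reports_to_json(reports, run_metadata=run_meta))
    logger.info("pipeline finished in %.2fs", time.monotonic() - t0)
    return {"tsv": tsv_path, "json": json_path, "out_dir": out,
            "reports": reports}


def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def _context_tree_records(query: ProteinRecord, db: Sequence[AllergenEntry],
                          full: FullScanSummary,
                          safe_set: Sequence[ProteinRecord],
                          max_allergens: int = 5,
                          ) -> list[ProteinRecord]:
    """Records for a context tree: query + top allergen hits + safe homologs."""
    by_id = {e.record.id: e.record for e in db}
    top = [h.subject_id for h in full.hits
           if h.evalue is not None and h.evalue < 10.0 and not h.is_empty]
    records = [query]
    for sid in top[:max_allergens]:
        if sid in by_id:
            records.append(by_id[sid])
    records.extend(safe_set)
    # drop duplicate ids while preserving order
    seen: set[str] = set()
    unique = []
    for r in records:
        if r.id not in seen:
            seen.add(r.id)
            unique.append(r)
    return unique
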