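"""On-disk formats for the crossover/crossback RE pipeline.

Everything is tab-separated text: sample sheets, expression matrices,
BED-derived annotation and results tables.  ``NA`` is the only missing-value
token and is legal only in covariate columns — never in expression cells.
All genomic coordinates are 0-based half-open internally.

The crossover design vocabulary lives here as module constants: two arms
(``B1HB2`` starts on background-DBP mesalamine, ``H1BH2`` on high-DBP),
three visit positions per subject, and the arm x visit lookup that fixes
each sample's DBP condition.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("B1HB2", "H1BH2")
VISITS = ("baseline", "crossover", "crossback")
CONDITIONS = ("background", "high_dbp")

#: DBP exposure implied by arm and visit position.  B1HB2 subjects start on
#: the background drug, switch to high-DBP at crossover and switch back;
#: H1BH2 subjects do the reverse.
CONDITION_TABLE = {
    ("B1HB2", "baseline"): "background",
    ("B1HB2", "crossover"): "high_dbp",
    ("B1HB2", "crossback"): "background",
    ("H1BH2", "baseline"): "high_dbp",
    ("H1BH2", "crossover"): "background",
    ("H1BH2", "crossback"): "high_dbp",
}

#: The nine adjustment covariates carried by every sample record.
COVARIATE_COLUMNS = [
    "batch",
    "months_on_dbp_prior",
    "bmi",
    "season_warm",
    "smoking",
    "age",
    "amplification_efficiency",
    "duplication_rate",
    "alignment_rate",
]

REQUIRED_SAMPLE_COLUMNS = ["sample_id", "subject_id", "arm", "visit", "condition"]
OPTIONAL_SAMPLE_COLUMNS = ["input_reads", "qc_pass"]

_FRACTION_COLUMNS = ("duplication_rate", "alignment_rate")

RE_CLASSES = ("exonic", "near_exon", "intronic", "orphan")


class StudyIOError(ValueError):
    """Raised for malformed or internally inconsistent study files."""


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values with their unit.

    ``data`` is a features-by-samples DataFrame; ``unit`` is ``"RPKM"``
    (long-RNA elements) or ``"RPM"`` (small RNAs).  Values are finite and
    non-negative by construction.
    """

    data: pd.DataFrame
    unit: str = "RPKM"

    def __post_init__(self):
        if self.unit not in ("RPKM", "RPM"):
            raise StudyIOError(f"unknown expression unit {self.unit!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise StudyIOError(
                f"non-finite expression at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise StudyIOError(
                f"negative expression at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise StudyIOError("duplicate feature or sample identifiers")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.unit)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory sample sheet; returns it unchanged on success."""
    for col in REQUIRED_SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise StudyIOError(f"sample sheet missing required column {col!r}")
    if samples.empty:
        raise StudyIOError("sample sheet contains no samples")
    dup = samples["sample_id"][samples["sample_id"].duplicated()]
    if len(dup):
        raise StudyIOError(f"duplicate sample_id {dup.iloc[0]!r}")
    for row in samples.itertuples():
        if row.arm not in ARMS:
            raise StudyIOError(f"row {row.sample_id!r}: unknown arm {row.arm!r}")
        if row.visit not in VISITS:
            raise StudyIOError(f"row {row.sample_id!r}: unknown visit {row.visit!r}")
        expected = CONDITION_TABLE[(row.arm, row.visit)]
        if row.condition != expected:
            raise StudyIOError(
                f"row {row.sample_id!r}: condition {row.condition!r} contradicts "
                f"arm {row.arm} x visit {row.visit} (expected {expected!r})"
            )
    for col in _FRACTION_COLUMNS:
        if col in samples.columns:
            vals = pd.to_numeric(samples[col], errors="coerce").dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise StudyIOError(f"column {col!r} outside [0, 1]")
    return samples


def read_sample_sheet(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise StudyIOError(f"{path}: empty sample sheet")
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str},
                          na_values=["NA"], keep_default_na=False)
    validate_sample_sheet(samples)
    logger.info("read %d samples from %s", len(samples), path)
    return samples


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    validate_sample_sheet(samples)
    samples.to_csv(path, sep="\t", index=False, na_rep="NA")


def qc_passed(samples: pd.DataFrame) -> pd.DataFrame:
    """Samples admitted to modelling (failed samples are kept on disk for
    reporting but never enter a fit)."""
    if "qc_pass" not in samples.columns:
        return samples
    kept = samples[samples["qc_pass"].astype(bool)]
    logger.info("qc filter: %d of %d samples retained", len(kept), len(samples))
    return kept


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_matrix(path, unit: str = "RPKM") -> ExpressionMatrix:
    """Read a features-by-samples TSV matrix (first column = feature id)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[],
                            keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise StudyIOError(f"{path}: ragged or unparseable matrix ({exc})") from exc
    if frame.empty:
        raise StudyIOError(f"{path}: empty matrix")
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise StudyIOError(
            f"{path}: non-numeric or missing expression cell at feature "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    frame = coerced
    try:
        return ExpressionMatrix(frame, unit)
    except StudyIOError as exc:
        raise StudyIOError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.data.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotation (BED6 + class, repeat_names [, gene_symbols])
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["chrom", "start", "end", "re_id", "score", "strand",
                      "re_class", "repeat_names", "gene_symbols"]


def _split_names(token: str) -> list[str]:
    return [] if token in (".", "") else token.split(",")


def read_bed_annotation(path) -> pd.DataFrame:
    """Read RE annotation as BED6 plus class and repeat-name columns.

    A ninth ``gene_symbols`` column is optional.  Coordinates are 0-based
    half-open; ``repeat_names``/``gene_symbols`` become Python lists.
    """
    rows = pd.read_csv(path, sep="\t", header=None, comment="#",
                       na_values=[], keep_default_na=False)
    if rows.shape[1] not in (8, 9):
        raise StudyIOError(f"{path}: expected 8 or 9 columns, got {rows.shape[1]}")
    rows.columns = ANNOTATION_COLUMNS[: rows.shape[1]]
    if rows.shape[1] == 8:
        rows["gene_symbols"] = "."
    rows["start"] = rows["start"].astype(int)
    rows["end"] = rows["end"].astype(int)
    bad = rows[rows["start"] >= rows["end"]]
    if len(bad):
        r = bad.iloc[0]
        raise StudyIOError(
            f"{path}: interval start >= end for {r['re_id']!r} ({r['start']} >= {r['end']})"
        )
    unknown = set(rows["re_class"]) - set(RE_CLASSES)
    if unknown:
        raise StudyIOError(f"{path}: unknown RE class {sorted(unknown)[0]!r}")
    rows["repeat_names"] = rows["repeat_names"].map(_split_names)
    rows["gene_symbols"] = rows["gene_symbols"].map(_split_names)
    return rows.set_index("re_id", drop=False)


def write_bed_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    for col in ("repeat_names", "gene_symbols"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: ",".join(v) if len(v) else ".")
        else:
            out[col] = "."
    cols = ["chrom", "start", "end", "re_id", "score", "strand",
            "re_class", "repeat_names", "gene_symbols"]
    out[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# results + manifest
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_results(tables: dict[str, pd.DataFrame], out_dir, *,
                  config: dict | None = None, seed: int | None = None) -> Path:
    """Write one TSV per results table plus a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
        logger.info("wrote %s (%d rows)", out_dir / f"{name}.tsv", len(table))
    from . import __version__

    manifest = {
        "package": "crossback-re",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config or {}),
        "tables": sorted(tables),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_dir


def read_manifest(run_dir) -> dict:
    return json.loads((Path(run_dir) / "manifest.json").read_text())
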