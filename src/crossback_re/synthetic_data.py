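"""Synthetic crossover-study designs and expression matrices with known truth.

The generator emulates the structure the differential pipeline assumes: two
study arms (B1HB2 enters on background-DBP mesalamine, H1BH2 on high-DBP),
three visits per subject (baseline, crossover, crossback) with missing and
replicate visits, per-subject random intercepts, covariate effects, and
planted visit or condition effects for each named response class.  Default
arm sizes (16 B1HB2, 19 H1BH2) mirror the subjects with consecutive visit
pairs in the study the design models.

Expression noise is Gaussian on the RPKM/RPM scale with clipping at zero —
the same scale the linear models consume — rather than count-based, so the
planted slope is exactly the estimand of the downstream model.  Replicate
visits share their subject's intercept and planted effects and re-draw only
per-sample quantities (residual and technical covariates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .re_annotation import GeneModel, annotate_loci, classify_re
from .study_io import CONDITION_TABLE, ExpressionMatrix, VISITS

logger = logging.getLogger(__name__)

#: sign of (delta_t1, delta_t2) per response class; None entries are zero.
_CLASS_SIGNS = {
    "acute_up": (1, 0),
    "acute_down": (-1, 0),
    "recovery_up": (0, 1),
    "recovery_down": (0, -1),
    "continuous_up": (1, 1),
    "continuous_down": (-1, -1),
    "reversal_up_down": (1, -1),
    "reversal_down_up": (-1, 1),
    "none": (0, 0),
}

#: condition-planted classes for the small-RNA generator.
_CONDITION_SIGNS = {"condition_up": 1, "condition_down": -1, "none": 0}

BATCH_LEVELS = ("batch1", "batch2", "batch3")


class SpecError(ValueError):
    """Invalid generator specification."""


@dataclass
class StudyDesignSpec:
    """Arm sizes, visit missingness/replication and the master seed."""

    n_subjects_arm_bhb: int = 16
    n_subjects_arm_hbh: int = 19
    p_missing_visit: float | dict = 0.15
    p_replicate_visit: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_arm_bhb < 0 or self.n_subjects_arm_hbh < 0:
            raise SpecError("subject counts must be non-negative")
        if self.n_subjects_arm_bhb == 0 and self.n_subjects_arm_hbh == 0:
            raise SpecError("at least one arm must have subjects")
        for v in self._missing_map().values():
            if not 0 <= v <= 1:
                raise SpecError("p_missing_visit must lie in [0, 1]")
        if not 0 <= self.p_replicate_visit <= 1:
            raise SpecError("p_replicate_visit must lie in [0, 1]")

    def _missing_map(self) -> dict[str, float]:
        if isinstance(self.p_missing_visit, dict):
            unknown = set(self.p_missing_visit) - set(VISITS)
            if unknown:
                raise SpecError(f"unknown visit in p_missing_visit: {unknown}")
            return {v: float(self.p_missing_visit.get(v, 0.0)) for v in VISITS}
        return {v: float(self.p_missing_visit) for v in VISITS}


@dataclass
class NoiseSpec:
    """Variance components and covariate coefficients of the generative model.

    ``covariate_effects`` maps a numeric covariate name to its linear
    coefficient (expression units per covariate unit); the key ``batch``
    may map to a dict of per-level offsets.
    """

    subject_intercept_sd: float = 10.0
    residual_sd: float = 5.0
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.subject_intercept_sd < 0 or self.residual_sd < 0:
            raise SpecError("standard deviations must be non-negative")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(spec: StudyDesignSpec) -> pd.DataFrame:
    """Sample sheet for a two-arm crossover/crossback design.

    Subjects are assigned covariates, visits are dropped with the
    per-visit missingness probability, and retained visits gain a second
    (replicate) sample with ``p_replicate_visit``.  Identical seeds give
    identical sheets.
    """
    rng = np.random.default_rng(spec.seed)
    missing = spec._missing_map()
    rows = []
    subjects = [("B1HB2", f"bhb{i + 1:02d}") for i in range(spec.n_subjects_arm_bhb)]
    subjects += [("H1BH2", f"hbh{i + 1:02d}") for i in range(spec.n_subjects_arm_hbh)]
    for arm, subject in subjects:
        age = max(18.0, rng.normal(35.0, 8.0))
        bmi = max(16.0, rng.normal(27.0, 4.0))
        smoking = int(rng.random() < 0.2)
        months_prior = float(np.round(rng.uniform(3, 60), 1)) if arm == "H1BH2" else 0.0
        for visit in VISITS:
            if rng.random() < missing[visit]:
                continue
            n_rep = 2 if rng.random() < spec.p_replicate_visit else 1
            for rep in range(1, n_rep + 1):
                suffix = "" if rep == 1 else f"_rep{rep}"
                rows.append({
                    "sample_id": f"{subject}_{visit}{suffix}",
                    "subject_id": subject,
                    "arm": arm,
                    "visit": visit,
                    "condition": CONDITION_TABLE[(arm, visit)],
                    "batch": BATCH_LEVELS[rng.integers(len(BATCH_LEVELS))],
                    "months_on_dbp_prior": months_prior,
                    "bmi": round(bmi, 1),
                    "season_warm": int(rng.random() < 0.5),
                    "smoking": smoking,
                    "age": round(age, 1),
                    "amplification_efficiency": round(rng.beta(20, 5), 4),
                    "duplication_rate": round(rng.beta(2, 8), 4),
                    "alignment_rate": round(rng.beta(30, 3), 4),
                    "qc_pass": 1,
                })
    design = pd.DataFrame(rows)
    if design.empty:
        raise SpecError("design generated no samples (missingness too high?)")
    logger.info("generated design: %d samples, %d subjects",
                len(design), design["subject_id"].nunique())
    return design


# ---------------------------------------------------------------------------
# truth assignment
# ---------------------------------------------------------------------------

def _feature_ids(n_features: int) -> list[str]:
    return [f"re_{i:06d}" for i in range(n_features)]


def _assign_classes(n_features: int, truth_fractions: dict, rng,
                    valid_classes) -> np.ndarray:
    fracs = dict(truth_fractions)
    unknown = set(fracs) - set(valid_classes)
    if unknown:
        raise SpecError(f"unknown response class in truth_fractions: {unknown}")
    if sum(fracs.values()) > 1 + 1e-9:
        raise SpecError("truth fractions sum to more than 1")
    classes = np.array(["none"] * n_features, dtype=object)
    order = rng.permutation(n_features)
    pos = 0
    for cls in sorted(fracs):
        k = int(round(fracs[cls] * n_features))
        classes[order[pos:pos + k]] = cls
        pos += k
    return classes


def _covariate_shift(design: pd.DataFrame, effects: dict) -> np.ndarray:
    shift = np.zeros(len(design))
    for cov, coef in effects.items():
        if isinstance(coef, dict):
            shift += design[cov].map(coef).fillna(0.0).to_numpy(dtype=float)
        else:
            shift += coef * pd.to_numeric(design[cov]).to_numpy(dtype=float)
    return shift


def _assemble(design, base, intercept_sd, resid_sd, planted, cov_shift, rng,
              unit) -> ExpressionMatrix:
    """base[f] + subject intercept[f,s] + covariates + planted[f,sample] + noise."""
    subj_codes, _ = pd.factorize(design["subject_id"])
    n_subjects = subj_codes.max() + 1
    F, N = planted.shape
    intercepts = rng.normal(0.0, intercept_sd, size=(F, n_subjects))
    resid = rng.normal(0.0, resid_sd, size=(F, N))
    values = base[:, None] + intercepts[:, subj_codes] + cov_shift[None, :] \
        + planted + resid
    clipped = float((values < 0).mean())
    values = np.clip(values, 0.0, None)
    if clipped >= 0.05:
        logger.warning("%.1f%% of synthetic values clipped at zero", 100 * clipped)
    frame = pd.DataFrame(values, index=_feature_ids(F),
                         columns=design["sample_id"].to_numpy())
    matrix = ExpressionMatrix(frame, unit)
    matrix.data.attrs["clipped_fraction"] = clipped
    return matrix


def generate_long_matrix(design: pd.DataFrame, n_features: int,
                         truth_fractions: dict, noise: NoiseSpec, seed: int,
                         effect_size: float = 30.0,
                         baseline_range: tuple = (50.0, 150.0),
                         condition_deltas: dict | None = None
                         ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Long-RNA (RPKM) matrix with visit effects planted per response class.

    The planted value at each visit position is cumulative: baseline 0,
    crossover delta_t1, crossback delta_t1 + delta_t2, with delta signs
    fixed by the class and magnitude ``effect_size``.  ``condition_deltas``
    optionally adds a per-feature offset applied to every high-DBP sample
    (used to emulate exposure-linked feature groups such as repeat REs).
    """
    if n_features < 1:
        raise SpecError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    classes = _assign_classes(n_features, truth_fractions, rng, _CLASS_SIGNS)
    s1 = np.array([_CLASS_SIGNS[c][0] for c in classes], dtype=float)
    s2 = np.array([_CLASS_SIGNS[c][1] for c in classes], dtype=float)
    d1, d2 = s1 * effect_size, s2 * effect_size
    base = rng.uniform(*baseline_range, size=n_features)

    visit_idx = design["visit"].map({v: i for i, v in enumerate(VISITS)}).to_numpy()
    offsets = np.column_stack([np.zeros(n_features), d1, d1 + d2])  # F x 3
    planted = offsets[:, visit_idx]
    if condition_deltas:
        ids = _feature_ids(n_features)
        high = (design["condition"] == "high_dbp").to_numpy(dtype=float)
        cond = np.array([condition_deltas.get(f, 0.0) for f in ids])
        planted = planted + cond[:, None] * high[None, :]
    cov_shift = _covariate_shift(design, noise.covariate_effects)
    matrix = _assemble(design, base, noise.subject_intercept_sd,
                       noise.residual_sd, planted, cov_shift, rng, "RPKM")
    truth = pd.DataFrame({
        "feature_id": _feature_ids(n_features),
        "response_class": classes,
        "delta_t1": d1,
        "delta_t2": d2,
        "baseline_mean": base,
    })
    return matrix, truth


def generate_small_matrix(design: pd.DataFrame, n_features: int,
                          truth_fractions: dict, noise: NoiseSpec, seed: int,
                          effect_size: float = 10.0,
                          baseline_range: tuple = (20.0, 80.0),
                          read_depth_median: float = 150_000.0,
                          read_depth_log_sd: float = 0.8,
                          min_reads: int = 10_000
                          ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Small-RNA (RPM) matrix with effects planted on DBP *condition*.

    Truth classes are ``condition_up`` / ``condition_down`` / ``none``; the
    delta applies to every high-DBP sample of the arm.  Also draws
    per-library input-read counts (log-normal around ``read_depth_median``,
    floored at ``min_reads``) so the 50,000-read library filter is
    exercisable; returns ``(matrix, truth, design_with_reads)``.
    """
    if n_features < 1:
        raise SpecError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    classes = _assign_classes(n_features, truth_fractions, rng, _CONDITION_SIGNS)
    delta = np.array([_CONDITION_SIGNS[c] for c in classes], dtype=float) * effect_size
    base = rng.uniform(*baseline_range, size=n_features)
    high = (design["condition"] == "high_dbp").to_numpy(dtype=float)
    planted = delta[:, None] * high[None, :]
    cov_shift = _covariate_shift(design, noise.covariate_effects)
    matrix = _assemble(design, base, noise.subject_intercept_sd,
                       noise.residual_sd, planted, cov_shift, rng, "RPM")
    truth = pd.DataFrame({
        "feature_id": _feature_ids(n_features),
        "response_class": classes,
        "delta_t1": delta,
        "delta_t2": 0.0,
        "baseline_mean": base,
    })
    out_design = design.copy()
    mu = np.log(read_depth_median)
    reads = rng.lognormal(mu, read_depth_log_sd, size=len(design))
    out_design["input_reads"] = np.maximum(reads, min_reads).astype(int)
    return matrix, truth, out_design


# ---------------------------------------------------------------------------
# toy genome + annotation
# ---------------------------------------------------------------------------

REPEAT_NAMES = ("(AATGGAATGG)n", "GA-rich", "(TTTC)n", "MER1A")

_EXON_LEN = 300
_INTRON_LEN = 4000
_SPACING = 20_000
_ORIGIN = 50_000


def toy_gene_model(n_genes: int = 30, chroms=("chr1", "chr2")) -> GeneModel:
    """Regularly spaced two-exon genes with introns long enough to hold
    intronic REs clear of the near-exon window."""
    rows = []
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        start = _ORIGIN + (g // len(chroms)) * _SPACING
        gene = f"GENE{g + 1:04d}"
        rows.append((chrom, start, start + _EXON_LEN, gene))
        e2 = start + _EXON_LEN + _INTRON_LEN
        rows.append((chrom, e2, e2 + _EXON_LEN, gene))
    return GeneModel.from_exons(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"]))


def toy_repeat_model(gene_model: GeneModel,
                     names=REPEAT_NAMES) -> pd.DataFrame:
    """Repeat intervals in intron middles and intergenic gaps of the toy
    genome, cycling through ``names``."""
    rows = []
    k = 0
    for gene_row in gene_model.genes.itertuples():
        intron_mid = gene_row.start + _EXON_LEN + _INTRON_LEN // 2
        rows.append((gene_row.chrom, intron_mid, intron_mid + 200, names[k % len(names)]))
        k += 1
        inter = gene_row.end + (_SPACING - (gene_row.end - gene_row.start)) // 2
        rows.append((gene_row.chrom, inter, inter + 200, names[k % len(names)]))
        k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


_DEFAULT_CLASS_FRACTIONS = {"exonic": 0.4, "near_exon": 0.2,
                            "intronic": 0.25, "orphan": 0.15}


def generate_annotation(n_features: int, gene_model: GeneModel,
                        repeat_model: pd.DataFrame, seed: int,
                        class_fractions: dict | None = None,
                        near_window: int = 1000) -> pd.DataFrame:
    """Place ``n_features`` REs so that all four classes are represented and
    intronic/orphan features alternate onto repeat intervals.

    Stored classes are verified against :func:`classify_re` on the emitted
    coordinates, so a round trip through the classifier is exact.  With an
    empty gene model every feature is an orphan (warned, not an error).
    """
    rng = np.random.default_rng(seed)
    fracs = class_fractions or _DEFAULT_CLASS_FRACTIONS
    empty_genome = len(gene_model.exons) == 0
    if empty_genome:
        logger.warning("empty gene model: all synthetic REs will be orphan")
        fracs = {"orphan": 1.0}
    counts = {cls: int(round(f * n_features)) for cls, f in fracs.items()}
    targets = []
    for cls in ("exonic", "near_exon", "intronic", "orphan"):
        targets += [cls] * counts.get(cls, 0)
    targets = (targets + ["exonic" if not empty_genome else "orphan"] * n_features)
    targets = targets[:n_features]

    exons = gene_model.exons
    genes = gene_model.genes
    # repeat intervals that sit clear of exons/windows, usable for placement
    placeable = []
    for rep in repeat_model.itertuples():
        cls = (classify_re(rep.chrom, rep.start, rep.end, gene_model, near_window)
               if not empty_genome else "orphan")
        if cls in ("intronic", "orphan"):
            placeable.append((cls, rep))
    rep_cursor = 0

    rows = []
    for i, cls in enumerate(targets):
        feat_len = int(rng.integers(120, 280))
        placed = None
        if cls in ("intronic", "orphan") and placeable and i % 2 == 0:
            for probe in range(len(placeable)):
                cand_cls, rep = placeable[(rep_cursor + probe) % len(placeable)]
                if cand_cls == cls:
                    rep_cursor += probe + 1
                    placed = (rep.chrom, rep.start + 20, rep.start + 20 + feat_len)
                    break
        if placed is None:
            placed = _place_feature(cls, feat_len, exons, genes, rng, near_window,
                                    gene_model)
        chrom, start, end = placed
        got = classify_re(chrom, start, end, gene_model, near_window)
        if got != cls:
            raise SpecError(
                f"could not place a {cls} RE under this gene model "
                f"(candidate classified as {got})")
        rows.append((chrom, int(start), int(end), f"re_{i:06d}", 0, "."))
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "re_id",
                                       "score", "strand"])
    annotation = annotate_loci(loci, gene_model, repeat_model, near_window)
    return annotation.set_index("re_id", drop=False)


def _place_feature(cls, feat_len, exons, genes, rng, near_window, gene_model,
                   max_tries: int = 200):
    """Rejection-sample a position of the requested class; works for any
    gene model that geometrically admits the class."""
    for _ in range(max_tries):
        if cls == "exonic":
            ex = exons.iloc[rng.integers(len(exons))]
            start = int(ex["start"]) + 10
            cand = (ex["chrom"], start, min(start + feat_len, int(ex["end"]) + 50))
        elif cls == "near_exon":
            ex = exons.iloc[rng.integers(len(exons))]
            gap = int(rng.integers(20, max(21, near_window // 2)))
            start = int(ex["end"]) + gap
            cand = (ex["chrom"], start, start + min(feat_len, 150))
        elif cls == "intronic":
            g = genes.iloc[rng.integers(len(genes))]
            lo, hi = int(g["start"]), int(g["end"]) - feat_len
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            cand = (g["chrom"], start, start + feat_len)
        else:  # orphan: beyond a gene or anywhere on an empty genome
            if len(genes):
                g = genes.iloc[rng.integers(len(genes))]
                start = int(g["end"]) + near_window + 3000 + int(rng.integers(0, 8000))
                cand = (g["chrom"], start, start + feat_len)
            else:
                start = _ORIGIN + int(rng.integers(0, 10_000_000))
                cand = ("chr1", start, start + feat_len)
        if classify_re(*cand, gene_model, near_window) == cls:
            return cand
    return cand  # let the caller report the mismatch
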