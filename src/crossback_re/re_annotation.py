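"""RE class assignment and repeat/gene annotation by interval overlap.

RNA elements (REs) are contiguous expressed intervals discovered in sperm
RNA-seq.  Each is assigned one of four classes against a gene model, with a
deterministic priority::

    exonic    — overlaps >= 1 bp of any exon
    near_exon — within ``near_window`` bp of an exon (default 1 kb)
    intronic  — inside a gene body but not exonic/near-exon
    orphan    — none of the above (intergenic)

Strand is ignored throughout: sperm RNA is heavily fragmented, so the
element's genomic footprint, not its orientation, is what the classes
describe.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study_io import RE_CLASSES, StudyIOError

logger = logging.getLogger(__name__)

DEFAULT_NEAR_WINDOW = 1000


@dataclass
class GeneModel:
    """Exon intervals plus the gene bodies they imply.

    ``exons`` has columns chrom/start/end/gene; ``genes`` is derived as the
    per-gene span (min start to max end per chromosome).
    """

    exons: pd.DataFrame
    genes: pd.DataFrame

    @classmethod
    def from_exons(cls, exons: pd.DataFrame) -> "GeneModel":
        exons = exons.reset_index(drop=True)
        if len(exons) and (exons["start"] >= exons["end"]).any():
            raise StudyIOError("gene model contains an empty or inverted exon")
        if len(exons):
            genes = (
                exons.groupby(["chrom", "gene"], as_index=False)
                .agg(start=("start", "min"), end=("end", "max"))
            )[["chrom", "start", "end", "gene"]]
        else:
            genes = pd.DataFrame(columns=["chrom", "start", "end", "gene"])
        return cls(exons, genes)

    @classmethod
    def from_exon_bed(cls, path) -> "GeneModel":
        """Exon-level BED with the gene symbol in the name column."""
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        if bed.shape[1] < 4:
            raise StudyIOError(f"{path}: exon BED needs >= 4 columns")
        bed = bed.iloc[:, :4]
        bed.columns = ["chrom", "start", "end", "gene"]
        return cls.from_exons(bed)


def _per_chrom(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {chrom: sub for chrom, sub in frame.groupby("chrom")}


def classify_re(chrom: str, start: int, end: int, gene_model: GeneModel,
                near_window: int = DEFAULT_NEAR_WINDOW) -> str:
    """Classify one RE interval against the gene model."""
    if start >= end:
        raise StudyIOError(f"invalid RE interval [{start}, {end})")
    exons = gene_model.exons
    if len(exons) == 0:
        return "orphan"
    ex = exons[exons["chrom"] == chrom]
    if len(ex) == 0:
        logger.warning("chromosome %s absent from gene model; RE -> orphan", chrom)
        return "orphan"
    es = ex["start"].to_numpy()
    ee = ex["end"].to_numpy()
    if np.any((es < end) & (ee > start)):
        return "exonic"
    # half-open gap distance to the nearest exon on this chromosome
    gap = np.maximum(es - end, start - ee)
    if np.any(gap <= near_window):
        return "near_exon"
    genes = gene_model.genes[gene_model.genes["chrom"] == chrom]
    gs = genes["start"].to_numpy()
    ge = genes["end"].to_numpy()
    if np.any((gs < end) & (ge > start)):
        return "intronic"
    return "orphan"


def classify_loci(loci: pd.DataFrame, gene_model: GeneModel,
                  near_window: int = DEFAULT_NEAR_WINDOW) -> pd.Series:
    """Vectorised driver: one class per row of a chrom/start/end frame."""
    return pd.Series(
        [classify_re(r.chrom, r.start, r.end, gene_model, near_window)
         for r in loci.itertuples()],
        index=loci.index, name="re_class",
    )


def overlap_repeats(chrom: str, start: int, end: int,
                    repeats: pd.DataFrame) -> list[str]:
    """Sorted unique names of repeat intervals overlapping >= 1 bp.

    ``repeats`` is a BED-like frame with chrom/start/end/name (RepeatMasker
    style, e.g. ``(AATGGAATGG)n`` or ``GA-rich``).  Adjacent intervals
    (``end == start``) do not overlap under the half-open convention.
    """
    if len(repeats) == 0:
        return []
    sub = repeats[repeats["chrom"] == chrom]
    hit = sub[(sub["start"] < end) & (sub["end"] > start)]
    return sorted(set(hit["name"]))


def annotate_loci(loci: pd.DataFrame, gene_model: GeneModel,
                  repeats: pd.DataFrame,
                  near_window: int = DEFAULT_NEAR_WINDOW) -> pd.DataFrame:
    """Full annotation: class, overlapping gene symbols and repeat names."""
    out = loci.copy()
    out["re_class"] = classify_loci(loci, gene_model, near_window)
    exons_by_chrom = _per_chrom(gene_model.exons) if len(gene_model.exons) else {}
    symbols = []
    rep_names = []
    for r in loci.itertuples():
        ex = exons_by_chrom.get(r.chrom)
        if ex is None:
            symbols.append([])
        else:
            hit = ex[(ex["start"] < r.end) & (ex["end"] > r.start)]
            symbols.append(sorted(set(hit["gene"])))
        rep_names.append(overlap_repeats(r.chrom, r.start, r.end, repeats))
    out["gene_symbols"] = symbols
    out["repeat_names"] = rep_names
    counts = out["re_class"].value_counts().to_dict()
    logger.info("annotated %d REs: %s", len(out),
                {c: counts.get(c, 0) for c in RE_CLASSES})
    return out


def motility_overlap(significant_exonic: pd.DataFrame, gene_list) -> pd.DataFrame:
    """Overlap differential exonic REs with a sperm-motility gene list.

    ``significant_exonic`` needs ``gene_symbols`` (lists) and a direction
    column (``call`` or ``direction`` with values up/down).  ``gene_list``
    is an iterable of symbols or a path to a one-symbol-per-line file.
    Returns one row per (gene, direction), genes deduplicated.
    """
    if isinstance(gene_list, (str, bytes)) or hasattr(gene_list, "read_text"):
        from pathlib import Path

        lines = Path(gene_list).read_text().split()
        genes = {g.strip() for g in lines if g.strip()}
    else:
        genes = set(gene_list)
    if not genes:
        logger.warning("motility gene list is empty")
        return pd.DataFrame(columns=["gene", "direction"])
    dir_col = "call" if "call" in significant_exonic.columns else "direction"
    seen: set[tuple[str, str]] = set()
    for row in significant_exonic.itertuples():
        direction = getattr(row, dir_col)
        if direction not in ("up", "down"):
            continue
        for gene in row.gene_symbols:
            if gene in genes:
                seen.add((gene, direction))
    out = pd.DataFrame(sorted(seen), columns=["gene", "direction"])
    return out
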