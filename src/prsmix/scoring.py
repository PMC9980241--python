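"""Per-individual PRS computation from dosage matrices and harmonized scores.

A PRS is the weighted allele count ``score_n = sum_j dosage_nj * w_j`` over
the variants a harmonized score shares with the genotype panel. Missing
dosages are mean-imputed as twice the alt-allele frequency observed among the
non-missing entries of the same variant. Raw scores are never standardized
here; standardization is a training-time concern of the mixer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pgs_io import HarmonizedScoring, VariantKey

__all__ = [
    "GenotypeMatrix",
    "ScorePanel",
    "NoOverlapError",
    "compute_prs",
    "build_panel",
    "read_dosage_tsv",
    "read_vcf_dosages",
    "write_score_table",
]

logger = logging.getLogger(__name__)


class NoOverlapError(ValueError):
    """A score shares no variants with the genotype panel."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant keys.

    ``dosages`` entries lie in [0, 2]; missing entries are NaN.
    """

    sample_ids: list[str]
    variants: list[VariantKey]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def variant_index(self) -> dict[VariantKey, int]:
        return {key: j for j, key in enumerate(self.variants)}


@dataclass
class ScorePanel:
    """Samples x scores matrix of raw PRS values with per-score annotations."""

    sample_ids: list[str]
    score_ids: list[str]
    values: np.ndarray
    trait_labels: dict[str, str] = field(default_factory=dict)
    accuracy: dict[str, object] = field(default_factory=dict)
    n_overlap: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.score_ids)):
            raise ValueError("panel value matrix shape inconsistent with ids")
        if len(self.score_ids) and np.isnan(self.values).all(axis=0).any():
            raise ValueError("panel contains an all-missing score column")

    def column(self, score_id: str) -> np.ndarray:
        return self.values[:, self.score_ids.index(score_id)]

    def subset_scores(self, score_ids: Sequence[str]) -> "ScorePanel":
        idx = [self.score_ids.index(s) for s in score_ids]
        return ScorePanel(
            sample_ids=self.sample_ids,
            score_ids=list(score_ids),
            values=self.values[:, idx],
            trait_labels={s: self.trait_labels.get(s, "") for s in score_ids},
            accuracy={s: self.accuracy[s] for s in score_ids if s in self.accuracy},
            n_overlap={s: self.n_overlap[s] for s in score_ids if s in self.n_overlap},
        )

    def subset_samples(self, indices: Sequence[int]) -> "ScorePanel":
        indices = list(indices)
        return ScorePanel(
            sample_ids=[self.sample_ids[i] for i in indices],
            score_ids=list(self.score_ids),
            values=self.values[indices, :],
            trait_labels=dict(self.trait_labels),
            accuracy=dict(self.accuracy),
            n_overlap=dict(self.n_overlap),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.score_ids)


def compute_prs(
    genotypes: GenotypeMatrix, scoring: HarmonizedScoring
) -> tuple[np.ndarray, int]:
    """Weighted allele-dosage sum for one harmonized score.

    Returns the per-sample score vector and the number of overlapping
    variants. Missing dosages contribute ``2 * alt_freq * weight``.
    """
    index = genotypes.variant_index()
    cols: list[int] = []
    weights: list[float] = []
    for rec in scoring.records.itertuples(index=False):
        key = VariantKey(rec.chrom, int(rec.pos), rec.ref, rec.alt)
        j = index.get(key)
        if j is not None:
            cols.append(j)
            weights.append(rec.weight)
    if not cols:
        raise NoOverlapError(
            f"score {scoring.score_id!r} shares no variants with the genotype panel"
        )
    dos = genotypes.dosages[:, cols]
    if np.isnan(dos).any():
        fill = 2.0 * genotypes.alt_frequency()[cols]
        dos = np.where(np.isnan(dos), fill[None, :], dos)
    return dos @ np.asarray(weights, dtype=float), len(cols)


def build_panel(
    genotypes: GenotypeMatrix, scorings: Sequence[HarmonizedScoring]
) -> ScorePanel:
    """Compute one panel column per harmonized score.

    Scores with zero variant overlap are omitted with a warning; if every
    score fails, an error is raised.
    """
    if not scorings:
        raise ValueError("no scorings supplied")
    columns: list[np.ndarray] = []
    score_ids: list[str] = []
    trait_labels: dict[str, str] = {}
    n_overlap: dict[str, int] = {}
    for scoring in scorings:
        try:
            vec, overlap = compute_prs(genotypes, scoring)
        except NoOverlapError:
            logger.warning(
                "score %s has no overlapping variants; omitted from panel",
                scoring.score_id,
            )
            continue
        columns.append(vec)
        score_ids.append(scoring.score_id)
        trait_labels[scoring.score_id] = scoring.trait_label
        n_overlap[scoring.score_id] = overlap
    if not columns:
        raise NoOverlapError("every score failed variant overlap with the panel")
    return ScorePanel(
        sample_ids=list(genotypes.sample_ids),
        score_ids=score_ids,
        values=np.column_stack(columns),
        trait_labels=trait_labels,
        n_overlap=n_overlap,
    )


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a samples x variants dosage TSV.

    First column is the sample id; remaining column headers are variant keys
    formatted ``chrom:pos:ref:alt``. Empty cells are missing dosages.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    variants = []
    for col in df.columns:
        chrom, pos, ref, alt = col.split(":")
        variants.append(VariantKey(chrom, int(pos), ref, alt))
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        variants=variants,
        dosages=df.to_numpy(dtype=float),
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    df = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=[str(k) for k in genotypes.variants],
    )
    df.to_csv(path, sep="\t")
    return Path(path)


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read dosages from a VCF, preferring DS over GT, restricted to bi-allelic SNVs."""
    from cyvcf2 import VCF  # optional dependency; only needed for VCF input

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        try:
            key = VariantKey(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        except ValueError:
            continue
        ds = rec.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gts[gts < 0] = np.nan
            dose = gts.sum(axis=1)
        variants.append(key)
        rows.append(dose)
    dosages = np.column_stack(rows) if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def write_score_table(panel: ScorePanel, path: str | Path) -> Path:
    """Write a per-sample score table (one column per score), .sscore-style."""
    panel.to_frame().to_csv(path, sep="\t")
    return Path(path)
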