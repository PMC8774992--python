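"""Per-gene TSS-window ChIP signal: counting, normalization, clustering,
divergence and chromosome-enrichment statistics, and conservative peaks.

Signal is called gene by gene: reads are counted in a symmetric window
around each annotated TSS (+-350 bp by default, a 700-bp extension
total) and each sample's vector is scaled to its own mean to remove
sequencing-depth differences. Replicate structure is assessed by PCA
over samples with a silhouette score of the factor labels; binding
divergence between factors by Euclidean distance between factor-mean
profiles with a replicate-permutation null; chromosome-level enrichment
(X versus autosomes) by the ratio of median normalized signal with a
gene-label permutation null. Peaks from two replicates are intersected
into a conservative set, and genes overlapping a conservative peak are
the bound genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .annotation import GeneModel

logger = logging.getLogger(__name__)

SENSITIVITY_HALF_WIDTHS = (100, 350, 500, 1000)


@dataclass
class SignalMatrix:
    """Genes x samples TSS-window counts with sample metadata."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    samples: pd.DataFrame  # index: sample ids; columns: factor, replicate
    half_width: int = 350

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValueError("counts must be non-negative")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match matrix columns")

    @property
    def factors(self) -> pd.Series:
        return self.samples["factor"]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start must be < end")


def peaks_from_frame(df: pd.DataFrame) -> list[Peak]:
    return [
        Peak(str(r.chrom), int(r.start), int(r.end), float(getattr(r, "score", 0)))
        for r in df.itertuples()
    ]


def tss_window_counts(
    reads: Mapping[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    samples: pd.DataFrame | None = None,
    half_width: int = 350,
    chrom_lengths: Mapping[str, int] | None = None,
) -> SignalMatrix:
    """Count read positions in the closed window [TSS-h, TSS+h] per gene.

    ``reads`` maps sample id -> frame with (chrom, pos) read positions;
    windows are truncated at chromosome edges when lengths are given.
    Genes on chromosomes absent from the length table are excluded with
    a log message.
    """
    usable = []
    for g in genes:
        if chrom_lengths is not None and g.chrom not in chrom_lengths:
            logger.warning("gene %s has no chromosome in the length table; excluded",
                           g.gene_id)
            continue
        usable.append(g)
    mat = {}
    for sample_id, frame in reads.items():
        pos_by_chrom = {
            c: np.sort(grp["pos"].to_numpy()) for c, grp in frame.groupby("chrom")
        }
        counts = np.zeros(len(usable), dtype=int)
        for i, g in enumerate(usable):
            lo = max(0, g.tss - half_width)
            hi = g.tss + half_width
            if chrom_lengths is not None:
                hi = min(hi, chrom_lengths[g.chrom] - 1)
            pos = pos_by_chrom.get(g.chrom)
            if pos is None:
                continue
            counts[i] = np.searchsorted(pos, hi, side="right") - np.searchsorted(
                pos, lo, side="left"
            )
        mat[sample_id] = counts
    values = pd.DataFrame(mat, index=[g.gene_id for g in usable])
    if samples is None:
        samples = pd.DataFrame(
            {"factor": list(values.columns), "replicate": 1}, index=values.columns
        )
    return SignalMatrix(values=values, samples=samples.loc[values.columns],
                        half_width=half_width)


def normalize_signal(matrix: SignalMatrix) -> SignalMatrix:
    """Scale each sample to its own mean; post-normalization means are 1."""
    means = matrix.values.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"cannot normalize all-zero sample(s): {bad}")
    return SignalMatrix(
        values=matrix.values / means,
        samples=matrix.samples,
        half_width=matrix.half_width,
    )


def pca_cluster_check(matrix: SignalMatrix, n_components: int = 2):
    """PCA over samples and silhouette of factor labels in PC1-PC2 space.

    Returns (coordinates DataFrame indexed by sample, silhouette score).
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("PCA check requires at least 3 samples")
    X = matrix.values.T.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    coords = PCA(n_components=k).fit_transform(X)
    labels = matrix.factors.to_numpy()
    sil = float(silhouette_score(coords[:, :2], labels)) if len(set(labels)) > 1 else float("nan")
    frame = pd.DataFrame(coords, index=matrix.values.columns,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return frame, sil


def _factor_mean_profiles(matrix: SignalMatrix) -> pd.DataFrame:
    return matrix.values.T.groupby(matrix.factors).mean().T


def protein_divergence(
    matrix: SignalMatrix,
    factor_a: str,
    factor_b: str,
    factor_ref: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Euclidean divergence of two factors from a reference factor.

    Returns (d(a, ref), d(b, ref), p) where p is the one-sided
    (+1-corrected) permutation probability of observing
    d(a, ref) - d(b, ref) at least as large under random reassignment of
    the a/b replicates.
    """
    rng = np.random.default_rng(seed)
    profiles = _factor_mean_profiles(matrix)
    ref = profiles[factor_ref].to_numpy()

    def dist(cols: Sequence[str]) -> float:
        return float(np.linalg.norm(matrix.values[cols].mean(axis=1).to_numpy() - ref))

    cols_a = list(matrix.samples.index[matrix.factors == factor_a])
    cols_b = list(matrix.samples.index[matrix.factors == factor_b])
    d_a, d_b = dist(cols_a), dist(cols_b)
    obs = d_a - d_b
    pool = cols_a + cols_b
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        exceed += (dist(list(perm[: len(cols_a)])) - dist(list(perm[len(cols_a):]))) >= obs
    p = (1 + exceed) / (1 + n_perm)
    return d_a, d_b, float(p)


def chromosome_enrichment(
    matrix: SignalMatrix,
    genes: Sequence[GeneModel],
    chrom_classes: Mapping[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-chromosome median normalized signal and X-vs-autosome tests.

    The enrichment statistic per factor is the ratio of the median
    normalized signal over X-linked genes to the median over autosomal
    genes; its p-value is the one-sided (+1-corrected) fraction of
    chromosome-label permutations (over genes) with a ratio at least as
    large. Returns (medians table: chromosomes x factors, p per factor).
    """
    rng = np.random.default_rng(seed)
    gene_chrom = pd.Series({g.gene_id: g.chrom for g in genes})
    gene_chrom = gene_chrom.loc[gene_chrom.index.intersection(matrix.values.index)]
    profiles = _factor_mean_profiles(matrix).loc[gene_chrom.index]
    medians = profiles.groupby(gene_chrom).median()
    classes = gene_chrom.map(lambda c: chrom_classes.get(c, "autosome"))
    is_x = (classes == "X").to_numpy()
    is_auto = (classes == "autosome").to_numpy()
    if is_x.sum() == 0 or is_auto.sum() == 0:
        raise ValueError("need genes on both X and autosomes")

    p_values = {}
    for factor in profiles.columns:
        v = profiles[factor].to_numpy()

        def ratio(x_mask: np.ndarray, auto_mask: np.ndarray) -> float:
            denom = np.median(v[auto_mask])
            return np.median(v[x_mask]) / denom if denom > 0 else np.inf

        obs = ratio(is_x, is_auto)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(v))
            exceed += ratio(is_x[perm], is_auto[perm]) >= obs
        p_values[factor] = (1 + exceed) / (1 + n_perm)
    return medians, pd.Series(p_values, name="p_x_vs_autosome")


def enrichment_ratio_contrast(
    matrix: SignalMatrix,
    genes: Sequence[GeneModel],
    chrom_classes: Mapping[str, str],
    factor_a: str,
    factor_b: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Is factor a's X/autosome enrichment larger than factor b's?

    Permutes replicate-to-factor assignment between the two factors;
    one-sided, +1-corrected.
    """
    rng = np.random.default_rng(seed)
    gene_chrom = pd.Series({g.gene_id: g.chrom for g in genes})
    gene_chrom = gene_chrom.loc[gene_chrom.index.intersection(matrix.values.index)]
    classes = gene_chrom.map(lambda c: chrom_classes.get(c, "autosome"))
    idx = gene_chrom.index
    is_x = (classes == "X").to_numpy()
    is_auto = (classes == "autosome").to_numpy()

    def enrich(cols: Sequence[str]) -> float:
        v = matrix.values.loc[idx, list(cols)].mean(axis=1).to_numpy()
        denom = np.median(v[is_auto])
        return np.median(v[is_x]) / denom if denom > 0 else np.inf

    cols_a = list(matrix.samples.index[matrix.factors == factor_a])
    cols_b = list(matrix.samples.index[matrix.factors == factor_b])
    obs = enrich(cols_a) - enrich(cols_b)
    pool = cols_a + cols_b
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        exceed += (enrich(perm[: len(cols_a)]) - enrich(perm[len(cols_a):])) >= obs
    return float(obs), float((1 + exceed) / (1 + n_perm))


def intersect_replicate_peaks(
    peaks_rep1: Sequence[Peak], peaks_rep2: Sequence[Peak]
) -> list[Peak]:
    """Conservative peak set: rep1 x rep2 intersection intervals, merged.

    Each rep1 peak overlapping a rep2 peak contributes the overlap
    interval; overlapping results are merged; output is sorted.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks_rep2:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    pieces: dict[str, list[tuple[int, int]]] = {}
    for p in peaks_rep1:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(p.start, p.end):
            pieces.setdefault(p.chrom, []).append(
                (max(p.start, iv.begin), min(p.end, iv.end))
            )
    out: list[Peak] = []
    for chrom in sorted(pieces):
        merged: list[list[int]] = []
        for s, e in sorted(pieces[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend(Peak(chrom, s, e) for s, e in merged)
    return out


def bound_genes(
    conservative_peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> set[str]:
    """Genes whose span overlaps at least one conservative peak."""
    trees: dict[str, IntervalTree] = {}
    for p in conservative_peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    out = set()
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is not None and tree.overlap(g.start, g.end):
            out.add(g.gene_id)
    return out


def rank_replicate_pairs(matrix: SignalMatrix, factor: str) -> list[tuple[str, str, float]]:
    """Replicate pairs of a factor ranked by Pearson signal correlation.

    Helper for choosing the 'two best replicates' whose peaks feed the
    conservative intersection.
    """
    cols = list(matrix.samples.index[matrix.factors == factor])
    corr = matrix.values[cols].corr()
    pairs = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(cols)
        for b in cols[i + 1:]
    ]
    return sorted(pairs, key=lambda t: -t[2])


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    stat: str = "mean",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided sampled-randomization test for a difference in mean/median.

    p = (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm), so p in (0, 1].
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    fn = np.mean if stat == "mean" else np.median
    rng = np.random.default_rng(seed)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    obs = abs(fn(a) - fn(b))
    pool = np.concatenate([a, b])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        exceed += abs(fn(perm[: len(a)]) - fn(perm[len(a):])) >= obs
    return float((1 + exceed) / (1 + n_perm))
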