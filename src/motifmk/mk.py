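"""Motif-level McDonald-Kreitman machinery.

The test contrasts fixed interspecies differences (D) with segregating
polymorphism (P) between motif-core sites and their immediate flanks,
using the flanks as the neutral reference in place of synonymous sites:

    alpha = 1 - (D_flank * P_core) / (D_core * P_flank)

interpreted as the proportion of core-site fixed differences driven by
positive selection. Uncertainty comes from a nonparametric bootstrap
whose resampling unit is the *segment* (all sites of a segment move
together, since sites within 21 bp are tightly linked); significance
from G and Fisher's exact tests on the 2x2 table; and specificity from
an empirical null in which every two-position shuffle of the motif is
pushed through the identical scan -> lift -> classify -> alpha pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from types import SimpleNamespace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSequence
from .orthomap import BlockMap, build_segments, classify_pairs, map_segments
from .scan import _min_distances, scan_motif

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["segment", "chrom", "pos", "site_class", "fixed_diff", "polymorphic"]


class UndefinedAlphaError(ValueError):
    """alpha is undefined when D_core = 0 or P_flank = 0."""


@dataclass(frozen=True)
class MKTable:
    """2x2 MK counts: fixed/polymorphic x core/flank sites."""

    D_core: int
    D_flank: int
    P_core: int
    P_flank: int
    stratum: str = "all"

    def __post_init__(self) -> None:
        if min(self.D_core, self.D_flank, self.P_core, self.P_flank) < 0:
            raise ValueError("MK counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.D_core, self.D_flank], [self.P_core, self.P_flank]])

    def __add__(self, other: "MKTable") -> "MKTable":
        return MKTable(
            self.D_core + other.D_core, self.D_flank + other.D_flank,
            self.P_core + other.P_core, self.P_flank + other.P_flank,
        )


@dataclass
class AlphaEstimate:
    """Point estimate of alpha with bootstrap CI and test p-values."""

    alpha: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    n_segments: int
    undefined_fraction: float
    p_g: float
    p_fisher: float
    p_boot: float  # one-sided bootstrap p for alpha > 0


def build_mk_table(
    site_records: pd.DataFrame,
    stratum_filter: Mapping[str, object] | Callable[[pd.DataFrame], pd.Series] | None = None,
    stratum: str = "all",
) -> MKTable:
    """Sum site records into the 2x2 table, optionally within a stratum.

    ``stratum_filter`` is either a column->value mapping (rows must match
    all) or a callable returning a boolean mask.
    """
    df = site_records
    if stratum_filter is not None and len(df):
        if callable(stratum_filter):
            df = df[stratum_filter(df)]
        else:
            mask = np.ones(len(df), dtype=bool)
            for col, val in stratum_filter.items():
                mask &= (df[col] == val).to_numpy()
            df = df[mask]
    if len(df) == 0:
        return MKTable(0, 0, 0, 0, stratum=stratum)
    core = df["site_class"] == "core"
    return MKTable(
        D_core=int(df.loc[core, "fixed_diff"].sum()),
        D_flank=int(df.loc[~core, "fixed_diff"].sum()),
        P_core=int(df.loc[core, "polymorphic"].sum()),
        P_flank=int(df.loc[~core, "polymorphic"].sum()),
        stratum=stratum,
    )


def alpha(table: MKTable) -> float:
    """alpha = 1 - (D_flank * P_core) / (D_core * P_flank)."""
    if table.D_core == 0 or table.P_flank == 0:
        raise UndefinedAlphaError(
            f"alpha undefined: D_core={table.D_core}, P_flank={table.P_flank}"
        )
    return 1.0 - (table.D_flank * table.P_core) / (table.D_core * table.P_flank)


def mk_tests(table: MKTable) -> tuple[float, float]:
    """G test (likelihood ratio, df 1, no continuity correction) and
    two-sided Fisher's exact p on the 2x2 table.

    With a zero margin Fisher returns 1 and the G statistic is undefined
    (returned as NaN with a warning).
    """
    arr = table.as_array()
    if arr.sum() == 0:
        raise ValueError("empty MK table")
    _, p_fisher = stats.fisher_exact(arr, alternative="two-sided")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.warning("G test undefined for table with a zero margin: %s", arr.tolist())
        return float("nan"), float(p_fisher)
    _, p_g, _, _ = stats.chi2_contingency(arr, correction=False,
                                          lambda_="log-likelihood")
    return float(p_g), float(p_fisher)


def segment_counts(site_records: pd.DataFrame) -> np.ndarray:
    """Per-segment (D_core, D_flank, P_core, P_flank) count matrix."""
    df = site_records
    core = (df["site_class"] == "core").to_numpy()
    agg = pd.DataFrame(
        dict(
            segment=df["segment"].to_numpy(),
            D_core=df["fixed_diff"].to_numpy() * core,
            D_flank=df["fixed_diff"].to_numpy() * ~core,
            P_core=df["polymorphic"].to_numpy() * core,
            P_flank=df["polymorphic"].to_numpy() * ~core,
        )
    ).groupby("segment").sum()
    return agg.to_numpy()


def _alpha_from_sums(sums: np.ndarray) -> np.ndarray:
    """Vectorized alpha over rows of (D_core, D_flank, P_core, P_flank); NaN
    where undefined."""
    d_core, d_flank, p_core, p_flank = sums.T.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 1.0 - (d_flank * p_core) / (d_core * p_flank)
    a[(d_core == 0) | (p_flank == 0)] = np.nan
    return a


def bootstrap_alpha(
    site_records: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.99,
    seed: int | np.random.Generator = 0,
) -> AlphaEstimate:
    """Segment-resampling bootstrap CI for alpha.

    Segments are drawn with replacement (all their sites together);
    the CI is the percentile interval at ``level``. Resamples with an
    undefined alpha are excluded from the percentiles and their fraction
    reported. ``p_boot`` is the one-sided (+1-corrected) bootstrap
    probability that alpha <= 0.
    """
    rng = np.random.default_rng(seed)
    counts = segment_counts(site_records)
    n_seg = counts.shape[0]
    if n_seg < 2:
        raise ValueError("bootstrap requires at least 2 segments")
    point = alpha(build_mk_table(site_records))
    p_g, p_fisher = mk_tests(build_mk_table(site_records))
    idx = rng.integers(0, n_seg, size=(n_boot, n_seg))
    sums = counts[idx].sum(axis=1)
    alphas = _alpha_from_sums(sums)
    valid = alphas[np.isfinite(alphas)]
    if valid.size == 0:
        raise ValueError("alpha undefined in every bootstrap resample")
    undef_frac = 1.0 - valid.size / n_boot
    if undef_frac > 0:
        logger.info("bootstrap_alpha: %.1f%% of resamples undefined", 100 * undef_frac)
    lo, hi = np.percentile(valid, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    p_boot = (1 + int(np.sum(valid <= 0.0))) / (1 + valid.size)
    return AlphaEstimate(
        alpha=float(point), ci_low=float(lo), ci_high=float(hi), level=level,
        n_boot=n_boot, n_segments=n_seg, undefined_fraction=float(undef_frac),
        p_g=p_g, p_fisher=p_fisher, p_boot=float(p_boot),
    )


def synonymous_reference_alpha(
    table: MKTable, synonymous_counts: tuple[int, int]
) -> float:
    """alpha with (D_syn, P_syn) replacing the flank reference counts.

    Synonymous divergence/polymorphism counts are an external input;
    their extraction from annotation is out of scope.
    """
    d_syn, p_syn = synonymous_counts
    return alpha(MKTable(table.D_core, d_syn, table.P_core, p_syn,
                         stratum=f"{table.stratum}|syn_ref"))


def annotate_site_records(
    site_records: pd.DataFrame,
    chrom_classes: Mapping[str, str],
    exons: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    within_bp: int = 1000,
) -> pd.DataFrame:
    """Add stratum columns: ``chrom_class`` and (with exons) ``location``.

    A segment is 'exonic' when its core interval lies within ``within_bp``
    of an annotated exon, 'intergenic' otherwise (the same 1-kb proximity
    rule as the exon-bias analysis).
    """
    df = site_records.copy()
    df["chrom_class"] = df["chrom"].map(lambda c: chrom_classes.get(c, "autosome"))
    if exons is not None and len(df):
        cores = (
            df[df["site_class"] == "core"]
            .groupby("segment")
            .agg(chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max"))
        )
        pseudo = [
            SimpleNamespace(chrom=r.chrom, start=int(r.start), end=int(r.end) + 1)
            for r in cores.itertuples()
        ]
        near = _min_distances(pseudo, exons) <= within_bp
        loc = pd.Series(
            np.where(near, "exonic", "intergenic"), index=cores.index
        )
        df["location"] = df["segment"].map(loc)
    return df


def stratified_alpha_contrast(
    site_records: pd.DataFrame,
    stratum_col: str,
    stratum_a: str,
    stratum_b: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Observed alpha_a - alpha_b with a segment-label permutation p-value.

    The null permutes stratum labels over segments; p is the two-sided
    (+1-corrected) fraction of |delta_perm| >= |delta_obs|. Errors if
    alpha is undefined in the observed data or in more than half of the
    permutations.
    """
    rng = np.random.default_rng(seed)
    seg_strata = (
        site_records.groupby("segment")[stratum_col].first()
    )
    seg_ids = seg_strata.index.to_numpy()
    labels = seg_strata.to_numpy()
    use = np.isin(labels, [stratum_a, stratum_b])
    if not use.any() or (labels[use] == stratum_a).sum() == 0 or (
        labels[use] == stratum_b
    ).sum() == 0:
        raise ValueError("both strata must be non-empty")
    records = site_records[site_records["segment"].isin(seg_ids[use])]
    counts = segment_counts(records)
    seg_order = np.sort(records["segment"].unique())
    lab = seg_strata.loc[seg_order].to_numpy()

    def delta(lab_vec: np.ndarray) -> float:
        a = _alpha_from_sums(counts[lab_vec == stratum_a].sum(axis=0)[None, :])[0]
        b = _alpha_from_sums(counts[lab_vec == stratum_b].sum(axis=0)[None, :])[0]
        return a - b

    obs = delta(lab)
    if not np.isfinite(obs):
        raise ValueError("alpha undefined in one of the observed strata")
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_deltas[i] = delta(rng.permutation(lab))
    finite = np.isfinite(perm_deltas)
    if finite.sum() < n_perm / 2:
        raise ValueError(
            f"alpha undefined in {n_perm - finite.sum()}/{n_perm} permutations; "
            "strata too small for a stable contrast"
        )
    exceed = np.sum(np.abs(perm_deltas[finite]) >= abs(obs))
    p = (1 + int(exceed)) / (1 + int(finite.sum()))
    return float(obs), float(p)


def shuffle_null_battery(
    src_genome: GenomeSequence,
    dst_genome: GenomeSequence,
    block_map: BlockMap,
    variants: pd.DataFrame,
    motifs: Sequence[str],
    focal_motif: str,
    flank_bp: int = 7,
    maf_min: float = 0.05,
    n_boot: int = 200,
    level: float = 0.99,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Run the full scan -> segment -> lift -> classify -> alpha pipeline for
    the focal motif and every control motif.

    Returns one row per motif (focal first) with alpha, CI, test
    p-values, a Bonferroni-adjusted bootstrap p over the battery size,
    and an ``is_focal`` flag; motifs with no usable data yield NaN rows.
    The summary attribute ``focal_exceeds_all`` (in ``df.attrs``) records
    whether the focal alpha exceeds every control alpha.
    """
    if len(motifs) == 0:
        raise ValueError("empty control motif set")
    rng = np.random.default_rng(seed)
    rows = []
    for motif in [focal_motif, *sorted(set(motifs) - {focal_motif})]:
        row: dict = dict(motif=motif, is_focal=motif == focal_motif)
        instances = scan_motif(src_genome, motif)
        segments = build_segments(instances, src_genome, flank_bp=flank_bp)
        pairs = map_segments(segments, block_map, src_genome, dst_genome)
        records = classify_pairs(pairs, variants, maf_min=maf_min)
        row["n_instances"] = len(instances)
        row["n_segments_mapped"] = sum(p.status == "mapped" for p in pairs)
        try:
            est = bootstrap_alpha(records, n_boot=n_boot, level=level,
                                  seed=rng.integers(2**31))
            row.update(
                alpha=est.alpha, ci_low=est.ci_low, ci_high=est.ci_high,
                p_g=est.p_g, p_fisher=est.p_fisher, p_boot=est.p_boot,
            )
        except (ValueError, UndefinedAlphaError) as exc:
            logger.info("battery motif %s: no data (%s)", motif, exc)
            row.update(alpha=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_g=np.nan, p_fisher=np.nan, p_boot=np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    n_tests = len(df)
    df["p_boot_bonferroni"] = np.minimum(df["p_boot"] * n_tests, 1.0)
    focal_alpha = df.loc[df["is_focal"], "alpha"].iloc[0]
    controls = df.loc[~df["is_focal"], "alpha"]
    df.attrs["focal_exceeds_all"] = bool(
        np.isfinite(focal_alpha)
        and (controls.dropna() < focal_alpha).all()
        and controls.notna().any()
    )
    return df
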