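"""Dosimetry analysis: ray profiles, region dose tables, energy flows, tPSF,
region-response correlation/clustering, and dose-response statistics.

The analysis layer turns raw Monte Carlo tallies into the quantities a
treatment-planning study reports: attenuation and fluence profiles along an
illumination ray, per-region energy deposition tables (percent of absorbed
and of launched energy), conserving source -> tissue -> region energy-flow
tables for Sankey diagrams, temporal point spread functions from time-gated
runs, and the statistical machinery (Pearson correlation, UPGMA clustering,
ordinary least squares, and the KS/Levene/t-test/Wilcoxon decision tree) used
for region-response and dose-response analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .optics import OpticalProperties, effective_attenuation
from .phantom import LabelAtlas, OpticalPhantom, ProbabilityMaps
from .transport import SimResult, SourceSpec, scale_to_physical

__all__ = [
    "RayProfile",
    "RegressionResult",
    "GroupCompareReport",
    "profile_along_ray",
    "response_matrix",
    "roi_dose",
    "energy_flow",
    "extract_tpsf",
    "pearson_matrix",
    "hierarchical_cluster",
    "linear_regression",
    "group_compare",
    "penetration_rate",
]


@dataclass
class RayProfile:
    """Sampled mueff and fluence-rate values along an illumination ray."""

    depths_mm: np.ndarray
    mueff: np.ndarray  # mm^-1
    fluence_rate: np.ndarray  # mW/mm^2 (physical) or per-photon if unscaled
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.depths_mm) > 0):
            raise ValueError("profile depths must be strictly increasing")
        if not len(self.depths_mm) == len(self.mueff) == len(self.fluence_rate):
            raise ValueError("profile arrays must have equal length")


def profile_along_ray(
    phantom: OpticalPhantom,
    result: SimResult | None,
    origin: np.ndarray,
    direction: np.ndarray,
    step_mm: float = 1.0,
    wavelength: float | None = None,
    physical: bool = True,
) -> RayProfile:
    """Sample mueff and fluence along a ray through the phantom.

    mueff is evaluated per sampled voxel from its (mua, mus, g); fluence is
    read from the simulation result (scaled to mW/mm^2 when ``physical``).
    Samples outside the grid are truncated.
    """
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("ray direction must be nonzero")
    direction = direction / nrm
    origin = np.asarray(origin, dtype=float)

    if wavelength is None:
        if result is not None and result.sources:
            wavelength = result.sources[0].wavelength
        else:
            wavelength = phantom.wavelengths[0]
    vols = phantom.properties(wavelength)

    if result is not None:
        flu = scale_to_physical(result)[0] if physical else result.fluence
    else:
        flu = None

    grid = phantom.grid
    max_t = float(np.linalg.norm(np.array(grid.shape) * np.array(grid.voxel_size))) + 1
    ts = np.arange(0.0, max_t, step_mm)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    vox = np.round(grid.world_to_voxel(pts)).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(grid.shape)), axis=1)
    if not inside.any():
        raise ValueError("ray does not intersect the grid")
    ts = ts[inside]
    vox = vox[inside]
    idx = tuple(vox.T)
    musp = (1.0 - vols["g"][idx]) * vols["mus"][idx]
    mueff = np.sqrt(3.0 * vols["mua"][idx] * (vols["mua"][idx] + musp))
    fl = flu[idx] if flu is not None else np.zeros(len(ts))
    return RayProfile(ts, mueff, fl, origin, direction)


def _absorbed_volume(result: SimResult) -> np.ndarray:
    return result.absorbed


def roi_dose(
    result: SimResult,
    atlas: LabelAtlas | None,
    tissue_maps: ProbabilityMaps | None,
    sources: Sequence[SourceSpec] | None = None,
) -> pd.DataFrame:
    """Per-region and per-tissue energy deposition summary table.

    Region deposition sums absorbed energy over atlas voxels; tissue-class
    deposition weights absorbed energy by class probability.  Both are
    reported as percent of total absorbed energy and percent of launched
    energy, alongside the mean fluence rate (physical units when sources have
    power) and region volume.  Regions with no voxels get a zero row with an
    ``empty`` flag.
    """
    sources = list(sources) if sources is not None else result.sources
    absorbed = _absorbed_volume(result)
    total_abs = absorbed.sum()
    flu_phys, _ = scale_to_physical(result, sources)
    vv = result.grid.voxel_volume
    rows = []

    def add(kind: str, name: str, dep: float, mean_flu: float, nvox: int) -> None:
        rows.append(
            {
                "kind": kind,
                "name": name,
                "pct_of_absorbed": 100.0 * dep / total_abs if total_abs > 0 else 0.0,
                "pct_of_launched": 100.0 * dep,
                "mean_fluence_mw_mm2": mean_flu,
                "volume_mm3": nvox * vv,
                "empty": nvox == 0,
            }
        )

    if atlas is not None:
        if not atlas.grid.compatible(result.grid):
            raise ValueError("atlas grid does not match simulation grid")
        labels = atlas.labels
        for lab, name in sorted(atlas.lookup.items()):
            sel = labels == lab
            nvox = int(sel.sum())
            dep = float(absorbed[sel].sum()) if nvox else 0.0
            mf = float(flu_phys[sel].mean()) if nvox else 0.0
            add("region", name, dep, mf, nvox)

    if tissue_maps is not None:
        if not tissue_maps.grid.compatible(result.grid):
            raise ValueError("tissue map grid does not match simulation grid")
        for cls, p in tissue_maps.maps.items():
            dep = float((absorbed * p).sum())
            wsum = p.sum()
            mf = float((flu_phys * p).sum() / wsum) if wsum > 0 else 0.0
            add("tissue", cls, dep, mf, int((p > 0).sum()))
        # remainder: energy absorbed outside the provided tissue classes
        ptot = tissue_maps.total()
        dep = float((absorbed * np.clip(1.0 - ptot, 0.0, 1.0)).sum())
        add("tissue", "remainder", dep, 0.0, int((ptot < 1 - 1e-9).sum()))

    return pd.DataFrame(rows)


def energy_flow(
    result: SimResult,
    atlas: LabelAtlas | None,
    tissue_maps: ProbabilityMaps,
    sources: Sequence[SourceSpec] | None = None,
) -> pd.DataFrame:
    """Conserving source -> tissue_class -> region energy-flow (Sankey) table.

    Requires per-source tallies (``SimConfig.per_source=True``).  Each flow
    row carries the absorbed energy fraction for one (source, tissue, region)
    triple; the table conserves energy at every node to floating point, with
    'unlabeled' catching voxels outside the atlas and 'remainder' catching
    probability mass outside the tissue classes.
    """
    if result.per_source_absorbed is None:
        raise ValueError(
            "per-source tallies missing: rerun run_mc with SimConfig(per_source=True)"
        )
    sources = list(sources) if sources is not None else result.sources
    labels = atlas.labels if atlas is not None else np.zeros(result.grid.shape, int)
    lookup = dict(atlas.lookup) if atlas is not None else {}
    lookup = {0: "unlabeled", **lookup}

    classes = list(tissue_maps.maps) + ["remainder"]
    pmaps = dict(tissue_maps.maps)
    pmaps["remainder"] = np.clip(1.0 - tissue_maps.total(), 0.0, 1.0)

    rows = []
    for si, absorbed in enumerate(result.per_source_absorbed):
        sname = f"source_{si}"
        for cls in classes:
            weighted = absorbed * pmaps[cls]
            for lab, rname in lookup.items():
                val = float(weighted[labels == lab].sum())
                if val > 0:
                    rows.append(
                        {
                            "source": sname,
                            "tissue": cls,
                            "region": rname,
                            "energy_fraction": val,
                        }
                    )
    return pd.DataFrame(rows, columns=["source", "tissue", "region", "energy_fraction"])


def response_matrix(
    result: SimResult, atlas: LabelAtlas, physical: bool = True
) -> pd.DataFrame:
    """Regions x sources matrix of mean fluence rate per region per source.

    Rows follow the atlas lookup order; requires per-source tallies
    (``SimConfig.per_source=True``).  ``physical`` scales each source's
    per-photon fluence by total source power (each per-source tally already
    carries its power share).
    """
    if result.per_source_fluence is None:
        raise ValueError(
            "per-source tallies missing: rerun run_mc with SimConfig(per_source=True)"
        )
    if not atlas.grid.compatible(result.grid):
        raise ValueError("atlas grid does not match simulation grid")
    total_power = sum(s.power_mw for s in result.sources) if physical else 1.0
    rows = {}
    for lab, name in sorted(atlas.lookup.items()):
        sel = atlas.labels == lab
        nvox = int(sel.sum())
        rows[name] = [
            float(pf[sel].mean()) * total_power if nvox else 0.0
            for pf in result.per_source_fluence
        ]
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"source_{i}" for i in range(len(result.per_source_fluence))],
    )
    if (out.to_numpy() < 0).any():
        raise ValueError("negative mean fluence in response matrix")
    return out


def extract_tpsf(result: SimResult, roi_mask: np.ndarray) -> np.ndarray:
    """Temporal point spread function: per-gate mean fluence over an ROI.

    The gate sum equals the steady-state ROI mean (arrival times partition
    the track-length tally).  An empty ROI returns an all-zero series.
    """
    if result.gated_fluence is None:
        raise ValueError("result has no time gates: rerun with SimConfig(n_gates >= 1)")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    nvox = int(roi_mask.sum())
    if nvox == 0:
        return np.zeros(result.gated_fluence.shape[0])
    return result.gated_fluence[:, roi_mask].mean(axis=1)


def pearson_matrix(m: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Pearson correlation of region response rows.

    Rows are regions, columns are sources (>= 2 required).  Constant rows
    have undefined correlations; those entries are reported as 0 (diagonal
    stays 1) rather than silently dropped.
    """
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("response matrix needs >= 2 source columns")
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.atleast_2d(corr)
    bad = sd == 0
    corr[bad, :] = 0.0
    corr[:, bad] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def hierarchical_cluster(
    matrix: np.ndarray | pd.DataFrame,
    n_clusters: int | None = None,
    linkage: str = "upgma",
    metric: str = "euclidean",
):
    """Agglomerative UPGMA (unweighted average Euclidean distance) clustering.

    Returns ``(merges, flat)`` where ``merges`` is the scipy-format linkage
    matrix (merge list with heights) and ``flat`` the partition labels at
    ``n_clusters`` (or None when not requested).
    """
    if linkage != "upgma":
        raise ValueError("only UPGMA (unweighted average) linkage is supported")
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    nan_rows = np.flatnonzero(np.any(~np.isfinite(arr), axis=1))
    if nan_rows.size:
        names = list(matrix.index[nan_rows]) if isinstance(matrix, pd.DataFrame) else nan_rows.tolist()
        raise ValueError(f"non-finite response rows for regions: {names}")
    Z = hierarchy.linkage(pdist(arr, metric=metric), method="average")
    flat = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, flat


@dataclass
class RegressionResult:
    """Simple OLS fit summary; R^2 equals the squared Pearson r."""

    slope: float
    intercept: float
    r2: float
    t_stat: float
    p_value: float
    n: int
    pearson_r: float


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y = a x + b with a two-tailed slope t-test (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = stats.linregress(x, y)
    se = fit.stderr
    t = fit.slope / se if se > 0 else math.inf
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        t_stat=float(t),
        p_value=float(fit.pvalue),
        n=int(x.size),
        pearson_r=float(fit.rvalue),
    )


@dataclass
class GroupCompareReport:
    """Outcome of the normality/variance-gated two-group comparison."""

    test: str  # "t", "paired_t", "wilcoxon_ranksum", "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    significant: bool
    ci95: tuple[float, float]
    reason: str
    ks_p: tuple[float, float]
    levene_p: float


def _ks_normal(sample: np.ndarray) -> float:
    mu = sample.mean()
    sd = sample.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(sample, "norm", args=(mu, sd)).pvalue)


def group_compare(
    a: np.ndarray, b: np.ndarray, paired: bool = False, alpha: float = 0.05
) -> GroupCompareReport:
    """Two-group comparison following the normality/variance decision tree.

    Both samples are tested for normality (Kolmogorov-Smirnov against a
    fitted normal, p > 0.05) and for equal variances (Levene, p > 0.05).  If
    both gates pass, an independent-samples t-test (or two-tailed paired
    t-test) is used; otherwise the Wilcoxon rank-sum (or signed-rank) test.
    Two-tailed p values; 95% confidence interval on the (mean or location)
    difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length samples")

    ks_a, ks_b = _ks_normal(a), _ks_normal(b)
    lev_p = float(stats.levene(a, b).pvalue)
    normal = ks_a > alpha and ks_b > alpha
    eqvar = lev_p > alpha

    diff = a - b if paired else None
    if normal and eqvar:
        if paired:
            if np.allclose(diff, 0):
                res_stat, res_p = 0.0, 1.0
            else:
                r = stats.ttest_rel(a, b)
                res_stat, res_p = float(r.statistic), float(r.pvalue)
            test = "paired_t"
            d = diff
            se = d.std(ddof=1) / math.sqrt(d.size) if d.size > 1 else 0.0
            tcrit = stats.t.ppf(1 - alpha / 2, d.size - 1)
            ci = (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se))
        else:
            r = stats.ttest_ind(a, b, equal_var=True)
            res_stat, res_p = float(r.statistic), float(r.pvalue)
            test = "t"
            nd = a.size + b.size - 2
            sp = math.sqrt(
                ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / nd
            )
            se = sp * math.sqrt(1 / a.size + 1 / b.size)
            tcrit = stats.t.ppf(1 - alpha / 2, nd)
            delta = a.mean() - b.mean()
            ci = (float(delta - tcrit * se), float(delta + tcrit * se))
        reason = f"KS p=({ks_a:.3g},{ks_b:.3g})>0.05 and Levene p={lev_p:.3g}>0.05"
    else:
        if paired:
            if np.allclose(diff, 0):
                res_stat, res_p = 0.0, 1.0
            else:
                r = stats.wilcoxon(a, b)
                res_stat, res_p = float(r.statistic), float(r.pvalue)
            test = "wilcoxon_signed_rank"
        else:
            r = stats.ranksums(a, b)
            res_stat, res_p = float(r.statistic), float(r.pvalue)
            test = "wilcoxon_ranksum"
        # distribution-free CI via the difference quantiles (coarse but honest)
        deltas = (a - b) if paired else (a[:, None] - b[None, :]).ravel()
        ci = (float(np.quantile(deltas, alpha / 2)), float(np.quantile(deltas, 1 - alpha / 2)))
        why = []
        if not normal:
            why.append(f"KS normality failed (p=({ks_a:.3g},{ks_b:.3g}))")
        if not eqvar:
            why.append(f"Levene failed (p={lev_p:.3g})")
        reason = "; ".join(why)

    return GroupCompareReport(
        test=test,
        statistic=res_stat,
        p_value=res_p,
        significant=res_p < alpha,
        ci95=ci,
        reason=reason,
        ks_p=(ks_a, ks_b),
        levene_p=lev_p,
    )


def penetration_rate(dose_table: pd.DataFrame) -> float:
    """Fraction of absorbed energy reaching past the extracerebral tissues.

    Defined as (energy deposited in gray matter + white matter + CSF) /
    (total absorbed energy); this package's operational definition of the
    'penetration rate through extracerebral tissues'.
    """
    tis = dose_table[dose_table["kind"] == "tissue"].set_index("name")
    inner = sum(
        tis.loc[c, "pct_of_absorbed"]
        for c in ("gray_matter", "white_matter", "csf")
        if c in tis.index
    )
    return float(inner / 100.0)
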