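"""Group statistics: global percentage changes and surface SPM.

Reproduces the trial's statistical surface: per-subject global percentage
change per metric (ratio of in-scope vertex means), group mean +/- SD with
three two-tailed t-test families (vs baseline, vs placebo, vs teriparatide),
baseline comparability by one-way ANOVA, and vertex-wise statistical
parametric maps with family-wise error controlled by permutation of the
maximum statistic (sign flips within group, label permutation between
groups).  Non-significant regions are displayed light gray; out-of-scope
regions (posterior elements for interior metrics) dark gray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .surface import BODY_ONLY_METRICS, SurfaceMesh, VertexMap

__all__ = [
    "CohortSummary",
    "SPMResult",
    "subject_percent_change",
    "summarize_cohort",
    "vertexwise_spm",
    "render_map",
]


@dataclass
class CohortSummary:
    """Per-group global change summary for one metric."""

    metric: str
    groups: dict  # group -> {"mean", "sd", "n", "p_vs_baseline"}
    p_between: dict = field(default_factory=dict)  # (a, b) -> p
    baseline_anova_p: float | None = None


@dataclass
class SPMResult:
    metric: str
    mean_change: np.ndarray       # per-vertex mean % change
    t_stat: np.ndarray
    significant: np.ndarray       # FWER-corrected mask
    in_scope: np.ndarray          # False = dark gray (region not examined)
    threshold: float
    alpha: float
    n_perm: int


def subject_percent_change(baseline: VertexMap, followup: VertexMap,
                           scope: np.ndarray | None = None,
                           *, min_valid_fraction: float = 0.5) -> float:
    """Global percentage change of one subject for one metric.

    Ratio of means over vertices that are in scope and valid at *both* time
    points (pairing avoids selection asymmetry between the scans):
    ``100 (mean_f - mean_b)/mean_b``.  Raises if fewer than
    ``min_valid_fraction`` of in-scope vertices are evaluable.
    """
    if len(baseline.values) != len(followup.values):
        raise ValueError("maps must be on the same (canonical) mesh")
    scope = np.ones(len(baseline.values), bool) if scope is None else scope
    ok = scope & baseline.valid & followup.valid
    if ok.sum() < min_valid_fraction * max(scope.sum(), 1):
        raise ValueError(
            f"subject evaluable on only {ok.sum()}/{scope.sum()} vertices")
    mb = baseline.values[ok].mean()
    mf = followup.values[ok].mean()
    return float(100.0 * (mf - mb) / mb)


def _one_sample_p(values: np.ndarray) -> float:
    values = np.asarray(values, float)
    if np.allclose(values, values[0]):
        # degenerate zero-variance group: exact-equality fast path
        return 1.0 if np.isclose(values[0], 0.0) else 0.0
    return float(sps.ttest_1samp(values, 0.0).pvalue)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        return 1.0 if np.isclose(a[0], b[0]) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def summarize_cohort(values_by_group: dict, metric: str = "",
                     baseline_by_group: dict | None = None) -> CohortSummary:
    """Group mean +/- SD of per-subject % changes with the three t families.

    vs-baseline: two-tailed one-sample t of the within-group changes against
    zero.  Between groups: two-tailed Welch t for every pair.  Baseline
    comparability (if baseline values are supplied): one-way ANOVA.
    """
    groups = {}
    for g, vals in values_by_group.items():
        vals = np.asarray(vals, float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
        groups[g] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n": int(len(vals)),
            "p_vs_baseline": _one_sample_p(vals),
        }
    p_between = {}
    names = list(values_by_group)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p_between[(a, b)] = _welch_p(values_by_group[a], values_by_group[b])
    anova_p = None
    if baseline_by_group is not None:
        arrays = [np.asarray(v, float) for v in baseline_by_group.values()]
        if all(np.allclose(a, arrays[0][0]) for a in arrays):
            anova_p = 1.0
        else:
            anova_p = float(sps.f_oneway(*arrays).pvalue)
    return CohortSummary(metric=metric, groups=groups, p_between=p_between,
                         baseline_anova_p=anova_p)


def _t_one_sample(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _t_welch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1) / na
    vb = B.var(axis=0, ddof=1) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(va + vb)
    return np.where(np.isfinite(t), t, 0.0)


def vertexwise_spm(change_maps: np.ndarray, *, groups: np.ndarray | None = None,
                   scope: np.ndarray | None = None, n_perm: int = 1000,
                   alpha: float = 0.05, seed: int = 0,
                   metric: str = "") -> SPMResult:
    """Vertex-wise t maps with permutation max-statistic FWER control.

    ``change_maps`` is (n_subjects, n_vertices) of per-subject canonical %
    changes.  Without ``groups`` the test is one-sample (within-group change
    vs zero) and the null is generated by random sign flips; with a
    two-level ``groups`` array it is a two-sample Welch test with group
    labels permuted.  The corrected mask keeps vertices whose |t| exceeds
    the (1 - alpha) quantile of the permutation distribution of the maximum
    |t| over in-scope vertices; the observed labelling is included in the
    null, making the test exact.  If ``n_perm`` exceeds the number of
    distinct permutations, they are enumerated exhaustively.
    """
    X = np.asarray(change_maps, float)
    n, n_vert = X.shape
    scope = np.ones(n_vert, bool) if scope is None else np.asarray(scope, bool)
    finite = np.isfinite(X).all(axis=0)
    scope = scope & finite
    rng = np.random.default_rng(seed)

    if groups is None:
        if n_perm < 500:
            raise ValueError("n_perm must be at least 500")
        t_obs = _t_one_sample(X)
        if 2**n <= n_perm:  # exhaustive sign flips
            signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n),
                                         indexing="ij")).reshape(n, -1).T
        else:
            signs = rng.choice([1.0, -1.0], size=(n_perm, n))
            signs[0] = 1.0  # include the observed labelling
        Xs = X[:, scope]
        max_t = np.array([np.abs(_t_one_sample(s[:, None] * Xs)).max()
                          for s in signs])
    else:
        groups = np.asarray(groups)
        lv = np.unique(groups)
        if len(lv) != 2:
            raise ValueError("two-sample SPM needs exactly two groups")
        ia, ib = groups == lv[0], groups == lv[1]
        t_obs = _t_welch(X[ia], X[ib])
        Xs = X[:, scope]
        idx = np.arange(n)
        from math import comb
        if comb(n, int(ia.sum())) <= n_perm:
            from itertools import combinations
            perms = [np.array(c) for c in combinations(idx, int(ia.sum()))]
        else:
            perms = [idx[:0]] * 0
            perms = [np.sort(rng.choice(idx, int(ia.sum()), replace=False))
                     for _ in range(n_perm)]
            perms[0] = idx[ia]  # observed labelling
        max_t = np.empty(len(perms))
        for k, pa in enumerate(perms):
            mb = np.ones(n, bool)
            mb[pa] = False
            max_t[k] = np.abs(_t_welch(Xs[pa], Xs[mb])).max()

    threshold = float(np.quantile(max_t, 1.0 - alpha))
    significant = scope & (np.abs(t_obs) > threshold)
    mean_change = X.mean(axis=0)
    return SPMResult(metric=metric, mean_change=mean_change, t_stat=t_obs,
                     significant=significant, in_scope=scope,
                     threshold=threshold, alpha=alpha, n_perm=len(max_t))


LIGHT_GRAY = (200, 200, 200)
DARK_GRAY = (80, 80, 80)


def render_map(result, mesh: SurfaceMesh, out_prefix: str,
               *, cmap: str = "turbo", vmin=None, vmax=None):
    """Write an SPM (or plain map) as mesh scalars plus a raster snapshot.

    Produces ``<prefix>.csv`` (vertex scalars + display class), ``<prefix>.ply``
    (vertex-coloured mesh) and ``<prefix>.png`` (matplotlib 3-D snapshot).
    Display convention: numeric colour where significant, light gray where
    not, dark gray where the region was not examined.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd
    import trimesh
    from matplotlib import cm as mcm

    if isinstance(result, SPMResult):
        values = result.mean_change
        show = result.significant
        scope = result.in_scope
        name = result.metric
    else:
        values = result.values
        show = result.valid
        scope = np.ones(len(values), bool)
        name = result.name

    vmin = np.nanmin(values[show]) if (vmin is None and show.any()) else (vmin or 0.0)
    vmax = np.nanmax(values[show]) if (vmax is None and show.any()) else (vmax or 1.0)
    norm = matplotlib.colors.Normalize(vmin=vmin, vmax=vmax)
    mapper = mcm.ScalarMappable(norm=norm, cmap=cmap)

    colors = np.tile(np.array(LIGHT_GRAY, dtype=np.uint8), (len(values), 1))
    colors[~scope] = DARK_GRAY
    rgba = (mapper.to_rgba(np.nan_to_num(values))[:, :3] * 255).astype(np.uint8)
    colors[show] = rgba[show]

    display = np.where(~scope, "dark_gray",
                       np.where(show, "value", "light_gray"))
    pd.DataFrame({
        "vertex_id": np.arange(len(values)),
        "value": values,
        "significant": show.astype(int),
        "in_scope": scope.astype(int),
        "display": display,
    }).to_csv(f"{out_prefix}.csv", index=False, float_format="%.17g")

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         vertex_colors=colors, process=False)
    tm.export(f"{out_prefix}.ply")

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    tri = mesh.faces
    face_col = colors[tri].mean(axis=1) / 255.0
    ax.plot_trisurf(mesh.vertices[:, 0], mesh.vertices[:, 1],
                    mesh.vertices[:, 2], triangles=tri, linewidth=0.1)
    ax.collections[0].set_facecolor(face_col)
    ax.set_title(name)
    ax.set_axis_off()
    fig.colorbar(mapper, ax=ax, shrink=0.6, label=name)
    fig.savefig(f"{out_prefix}.png", dpi=110)
    plt.close(fig)
    return f"{out_prefix}.csv"
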