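"""End-to-end cohort analysis drivers.

Glue between the stages: fit both time points of every subject with the
longitudinally coupled density constraint, assemble per-vertex metric maps,
compute per-subject global percentage changes, and summarize per group.
Profile-level cohorts (no 3-D volume, one profile per vertex) are the
workhorse for recovery experiments; the same flow applies to volume-level
subjects after :func:`bonemap.profiles.fit_surface`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import FitConfig, measure_profile_pair
from .stats import CohortSummary, subject_percent_change, summarize_cohort
from .surface import VertexMap

METRICS = ("ct_th", "ec_th", "ct_bmd", "cn_bmd", "cmsd")

__all__ = ["METRICS", "SubjectMeasurement", "CohortResult",
           "measure_subject_pair", "measure_volume_pair",
           "analyze_profile_cohort"]


@dataclass
class SubjectMeasurement:
    group: str
    subject_id: int
    maps_base: dict      # metric -> VertexMap
    maps_follow: dict
    pct_change: dict     # metric -> subject global % change
    info: dict


@dataclass
class CohortResult:
    subjects: list
    summaries: dict      # metric -> CohortSummary
    group_means: dict    # metric -> {group: recovered mean % change}

    def change_matrix(self, metric: str, group: str | None = None):
        """(n_subjects, n_vertices) per-vertex % change array for SPM."""
        rows, groups = [], []
        for s in self.subjects:
            if group is not None and s.group != group:
                continue
            b = self.maps(s, metric)[0]
            f = self.maps(s, metric)[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                pc = 100.0 * (f.values - b.values) / b.values
            pc[~(b.valid & f.valid)] = np.nan
            rows.append(pc)
            groups.append(s.group)
        return np.asarray(rows), np.asarray(groups)

    @staticmethod
    def maps(s: SubjectMeasurement, metric: str):
        return s.maps_base[metric], s.maps_follow[metric]


def _maps_from_results(results, n_vertices: int) -> dict:
    maps = {}
    for name in METRICS:
        values = np.full(n_vertices, np.nan)
        valid = np.zeros(n_vertices, dtype=bool)
        for r in results:
            if r.valid and 0 <= r.vertex_id < n_vertices:
                values[r.vertex_id] = getattr(r.metrics, name)
                valid[r.vertex_id] = True
        maps[name] = VertexMap(name=name, values=values, valid=valid)
    return maps


def measure_subject_pair(subject, config: FitConfig, *,
                         seed: int = 0) -> SubjectMeasurement:
    """Fit one subject's baseline/follow-up profile pair end to end."""
    res_b, res_f, info = measure_profile_pair(
        subject.profiles_base, subject.profiles_follow, config, seed=seed)
    n = len(subject.profiles_base)
    maps_b = _maps_from_results(res_b, n)
    maps_f = _maps_from_results(res_f, n)
    pct = {}
    for m in METRICS:
        try:
            pct[m] = subject_percent_change(maps_b[m], maps_f[m])
        except ValueError:
            # subject not evaluable for this metric (too few paired valid
            # vertices): flagged, excluded from group summaries
            pct[m] = np.nan
    return SubjectMeasurement(group=subject.group,
                              subject_id=subject.subject_id,
                              maps_base=maps_b, maps_follow=maps_f,
                              pct_change=pct, info=info)


def measure_volume_pair(volume_base, volume_follow, mesh,
                        run_config, *, seed: int = 0,
                        group: str = "", subject_id: int = -1
                        ) -> SubjectMeasurement:
    """Volume-level subject: sample profiles at both time points, fit with
    the longitudinally coupled density, smooth the maps across the surface
    (noise removal + fill-in of failed fits) and restrict interior metrics
    to the vertebral body."""
    from .surface import restrict_to_body, sample_profiles, smooth_vertex_map

    kw = dict(depth_out=run_config.depth_out, depth_in=run_config.depth_in,
              step=run_config.step)
    profs_b = sample_profiles(volume_base, mesh, **kw)
    profs_f = sample_profiles(volume_follow, mesh, **kw)
    config = run_config.fit_config()
    res_b, res_f, info = measure_profile_pair(profs_b, profs_f, config,
                                              seed=seed)
    n = len(mesh.vertices)
    maps_b = _maps_from_results(res_b, n)
    maps_f = _maps_from_results(res_f, n)
    pct = {}
    for m in METRICS:
        mb, mf = maps_b[m], maps_f[m]
        mb.mesh = mf.mesh = mesh
        if run_config.smoothing_fwhm > 0:
            mb = smooth_vertex_map(mb, run_config.smoothing_fwhm)
            mf = smooth_vertex_map(mf, run_config.smoothing_fwhm)
        mb = restrict_to_body(mb, mesh)
        mf = restrict_to_body(mf, mesh)
        maps_b[m], maps_f[m] = mb, mf
        scope = mesh.body_mask if m in ("cn_bmd", "ec_th") else None
        pct[m] = subject_percent_change(mb, mf, scope)
    return SubjectMeasurement(group=group, subject_id=subject_id,
                              maps_base=maps_b, maps_follow=maps_f,
                              pct_change=pct, info=info)


def analyze_profile_cohort(subjects, config: FitConfig | None = None, *,
                           seed: int = 0) -> CohortResult:
    """Measure every subject and summarize the per-group global changes."""
    config = config or FitConfig()
    measured = []
    for k, s in enumerate(subjects):
        measured.append(measure_subject_pair(s, config, seed=seed + 31 * k))

    summaries, group_means = {}, {}
    groups = sorted({s.group for s in measured},
                    key=lambda g: [s.group for s in measured].index(g))
    for m in METRICS:
        by_group = {g: [s.pct_change[m] for s in measured
                        if s.group == g and np.isfinite(s.pct_change[m])]
                    for g in groups}
        by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
        summaries[m] = summarize_cohort(by_group, metric=m)
        group_means[m] = {g: summaries[m].groups[g]["mean"] for g in by_group}
    return CohortResult(subjects=measured, summaries=summaries,
                        group_means=group_means)
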