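"""End-to-end orchestration: fit -> filter -> parameterize -> bin -> stats.

A *subject run* turns one multi-echo image plus tendon mask into a filtered
T2 map, a length-normalized T2 distribution profile and three segment
summaries.  A *cohort run* pairs pre- and post-treatment subject runs,
averages profiles across subjects with equal subject weight (so large
tendons do not dominate), fits per-segment regressions to the group
profiles, and compares visits with the Chow test (regression change) and
the Wilcoxon signed-rank test (paired segment means).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .phantom import (
    MultiEchoImage,
    PhantomConfig,
    PhantomTruth,
    generate_phantom,
)
from .profiling import (
    DEFAULT_R2_MIN,
    DEFAULT_T2_BOUNDS,
    SEGMENT_NAMES,
    FilterReport,
    LengthField,
    SegmentSummary,
    T2Profile,
    TendonMask,
    bin_profile,
    filter_t2_map,
    parameterize_length,
    segment_means,
    split_segments,
)
from .relaxometry import T2Map, compute_t2_map
from .stats import ChowResult, PairedSample, RegressionFit, chow_test, ols_fit, wilcoxon_signed_rank

__all__ = [
    "PipelineStageError",
    "SubjectResult",
    "CohortResult",
    "run_subject",
    "run_phantom_subject",
    "segment_regressions",
    "compare_profiles",
    "group_profile",
    "run_cohort",
    "cohort_phantom_configs",
]

logger = logging.getLogger(__name__)

_THIRD = 100.0 / 3.0
_SEGMENT_RANGES = {
    "lateral": (0.0, _THIRD),
    "middle": (_THIRD, 2 * _THIRD),
    "medial": (2 * _THIRD, 100.0),
}


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SubjectResult:
    """All per-subject pipeline outputs."""

    t2map: T2Map
    filtered: np.ndarray
    filter_report: FilterReport
    length: LengthField
    profile: T2Profile
    segments: list[SegmentSummary]

    def segment_mean(self, name: str) -> float:
        for s in self.segments:
            if s.segment == name:
                return s.mean_t2
        raise KeyError(name)

    def summary_dict(self) -> dict:
        return {
            "tendon_length_mm": self.length.tendon_length_mm,
            "filter": asdict(self.filter_report),
            "segments": [asdict(s) for s in self.segments],
        }


def run_subject(
    image: MultiEchoImage,
    mask: TendonMask,
    fit_method: str = "loglinear",
    t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    r2_min: float = DEFAULT_R2_MIN,
    n_bins: int = 100,
) -> SubjectResult:
    """Run the full single-subject pipeline in its canonical order.

    Stages: voxelwise decay fit, partial-volume/noise filter, geodesic
    length parameterization, profile binning, segment split and summary.
    Any stage failure is re-raised as :class:`PipelineStageError` naming
    the stage.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - tagged and re-raised
            raise PipelineStageError(name, exc) from exc

    t2map = stage("fit", compute_t2_map, image, mask.voxels, fit_method)
    filtered, report = stage("filter", filter_t2_map, t2map, mask, t2_bounds, r2_min)
    length = stage("parameterize", parameterize_length, mask, image.voxel_spacing)
    profile = stage("bin", bin_profile, t2map, filtered, length, n_bins)
    labels = stage("segment", split_segments, length)
    segments = stage("segment", segment_means, t2map, filtered, labels)
    n_seg = sum(s.n_voxels for s in segments)
    if n_seg != report.n_kept or int(profile.bin_counts.sum()) != report.n_kept:
        raise PipelineStageError(
            "segment",
            AssertionError("voxel bookkeeping mismatch across pipeline stages"),
        )
    return SubjectResult(
        t2map=t2map, filtered=filtered, filter_report=report,
        length=length, profile=profile, segments=segments,
    )


def run_phantom_subject(
    config: PhantomConfig, **pipeline_kwargs
) -> tuple[SubjectResult, PhantomTruth]:
    """Generate a phantom and push it through the subject pipeline."""
    image, truth = generate_phantom(config)
    mask = TendonMask(
        voxels=truth.mask,
        lateral_seed=truth.lateral_seed,
        medial_seed=truth.medial_seed,
    )
    return run_subject(image, mask, **pipeline_kwargs), truth


def _segment_bins(profile: T2Profile, lo: float, hi: float) -> np.ndarray:
    """Nonempty bins lying fully inside [lo, hi].

    Bins straddling a segment boundary mix voxels of two segments (the
    piecewise profile is discontinuous there) and are assigned to neither
    fit.
    """
    if len(profile.bin_centers) > 1:
        half = 0.5 * float(np.min(np.diff(profile.bin_centers)))
    else:
        half = 50.0
    return (
        profile.nonempty
        & np.isfinite(profile.bin_means)
        & (profile.bin_centers - half >= lo - 1e-9)
        & (profile.bin_centers + half <= hi + 1e-9)
    )


def segment_regressions(profile: T2Profile) -> dict[str, RegressionFit]:
    """Straight-line fit of the profile within each tendon third.

    Fits use nonempty bin means (unweighted) against bin centers, with x in
    the global percent coordinate; bins straddling a segment boundary are
    excluded (see :func:`_segment_bins`).
    """
    out: dict[str, RegressionFit] = {}
    for name, (lo, hi) in _SEGMENT_RANGES.items():
        sel = _segment_bins(profile, lo, hi)
        out[name] = ols_fit(profile.bin_centers[sel], profile.bin_means[sel])
    return out


def compare_profiles(
    before: T2Profile, after: T2Profile
) -> dict[str, dict]:
    """Per-segment regression parameters of two profiles plus the Chow test.

    The analog of reporting slope/intercept before and after treatment with
    a structural-change p-value per segment.
    """
    fits_a = segment_regressions(before)
    fits_b = segment_regressions(after)
    result: dict[str, dict] = {}
    for name, (lo, hi) in _SEGMENT_RANGES.items():
        def seg_xy(p: T2Profile) -> tuple[np.ndarray, np.ndarray]:
            sel = _segment_bins(p, lo, hi)
            return p.bin_centers[sel], p.bin_means[sel]

        chow = chow_test(seg_xy(before), seg_xy(after))
        result[name] = {
            "before": asdict(fits_a[name]),
            "after": asdict(fits_b[name]),
            "chow": asdict(chow),
        }
    return result


def group_profile(profiles: Sequence[T2Profile]) -> T2Profile:
    """Average subject profiles bin-wise with equal subject weight.

    A bin's group mean is the mean of the subject bin means over subjects
    with data in that bin; ``bin_counts`` is the number of contributing
    subjects.  All profiles must share one binning.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    centers = profiles[0].bin_centers
    for p in profiles[1:]:
        if not np.array_equal(p.bin_centers, centers):
            raise ValueError("profiles must share one binning")
    means = np.stack([p.bin_means for p in profiles])
    have = np.stack([p.bin_counts > 0 for p in profiles]) & np.isfinite(means)
    n_sub = have.sum(axis=0)
    with np.errstate(invalid="ignore"):
        g = np.where(n_sub > 0, np.nansum(np.where(have, means, 0.0), axis=0), np.nan)
        g = np.where(n_sub > 0, g / np.maximum(n_sub, 1), np.nan)
    return T2Profile(bin_centers=centers.copy(), bin_means=g, bin_counts=n_sub)


@dataclass
class CohortResult:
    """Group-level pre/post comparison.

    ``regression_table`` holds per-segment slope/intercept before and after
    plus the Chow p (group-profile regressions); ``segment_table`` holds
    per-segment mean +/- SD of the subject segment means with the Wilcoxon
    signed-rank p; ``subject_table`` is the per-subject long-format record.
    """

    regression_table: pd.DataFrame
    segment_table: pd.DataFrame
    subject_table: pd.DataFrame
    group_before: T2Profile
    group_after: T2Profile


def run_cohort(
    before: Sequence[SubjectResult],
    after: Sequence[SubjectResult],
    subject_ids: Optional[Sequence[str]] = None,
) -> CohortResult:
    """Compare paired pre/post subject runs at the group level.

    ``before[i]`` and ``after[i]`` must belong to the same subject.  At
    least 4 pairs are required for group statistics.
    """
    if len(before) != len(after):
        raise ValueError(
            f"unpaired cohort: {len(before)} pre vs {len(after)} post subjects"
        )
    n = len(before)
    if n < 4:
        raise ValueError(
            f"cohort of {n} pair(s): group statistics need at least 4 paired subjects"
        )
    ids = list(subject_ids) if subject_ids is not None else [f"S{i:02d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("subject_ids length must match the cohort size")

    g_before = group_profile([s.profile for s in before])
    g_after = group_profile([s.profile for s in after])
    comparison = compare_profiles(g_before, g_after)

    reg_rows, seg_rows, subj_rows = [], [], []
    for seg in SEGMENT_NAMES:
        c = comparison[seg]
        reg_rows.append(
            {
                "segment": seg,
                "slope_before": c["before"]["slope"],
                "intercept_before": c["before"]["intercept"],
                "slope_after": c["after"]["slope"],
                "intercept_after": c["after"]["intercept"],
                "chow_f": c["chow"]["f_stat"],
                "chow_p": c["chow"]["p_value"],
            }
        )
        pre_means = np.array([s.segment_mean(seg) for s in before])
        post_means = np.array([s.segment_mean(seg) for s in after])
        wres = wilcoxon_signed_rank(PairedSample(pre_means, post_means))
        seg_rows.append(
            {
                "segment": seg,
                "mean_before": float(np.mean(pre_means)),
                "sd_before": float(np.std(pre_means, ddof=1)),
                "mean_after": float(np.mean(post_means)),
                "sd_after": float(np.std(post_means, ddof=1)),
                "wilcoxon_w": wres.statistic,
                "wilcoxon_p": wres.p_value,
            }
        )
        for sid, visit, res in [
            *[(ids[i], "before", before[i]) for i in range(n)],
            *[(ids[i], "after", after[i]) for i in range(n)],
        ]:
            summ = next(s for s in res.segments if s.segment == seg)
            subj_rows.append(
                {
                    "subject": sid,
                    "visit": visit,
                    "segment": seg,
                    "mean_t2": summ.mean_t2,
                    "sd_t2": summ.sd_t2,
                    "n_voxels": summ.n_voxels,
                }
            )

    return CohortResult(
        regression_table=pd.DataFrame(reg_rows),
        segment_table=pd.DataFrame(seg_rows),
        subject_table=pd.DataFrame(subj_rows),
        group_before=g_before,
        group_after=g_after,
    )


def cohort_phantom_configs(
    n_subjects: int,
    profile_spec: tuple[tuple[float, float], ...],
    seed: int,
    base: Optional[PhantomConfig] = None,
) -> list[PhantomConfig]:
    """Per-subject phantom configs with anatomical variation.

    Each subject gets a jittered centerline (arc height, endpoints) and
    band thickness around the base geometry, plus an independent noise
    substream, while sharing the group's T2 profile — emulating a cohort
    of different tendons with one underlying group-level profile shape.
    """
    base = base or PhantomConfig()
    rng = np.random.default_rng(seed)
    configs = []
    (r0, c0), (r1, c1), (r2, c2) = base.centerline
    for i in range(n_subjects):
        jit = rng.normal(0.0, 2.0, size=6)
        cl = (
            (r0 + jit[0], c0 + jit[1]),
            (r1 + 2 * jit[2], c1 + jit[3]),
            (r2 + jit[4], c2 + jit[5]),
        )
        configs.append(
            base.with_(
                centerline=cl,
                half_thickness=float(np.clip(base.half_thickness + rng.normal(0, 0.5), 2.5, 6.0)),
                profile_spec=profile_spec,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return configs


def write_subject_report(
    result: SubjectResult, outdir: Path, config_fingerprint: str, seed: int
) -> None:
    """Write profile CSV, segment JSON and a provenance manifest."""
    from .io import save_profile_csv  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_profile_csv(result.profile, outdir / "profile.csv")
    (outdir / "segments.json").write_text(
        json.dumps(result.summary_dict(), indent=2, sort_keys=True)
    )
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "config_sha256": config_fingerprint,
                "seed": seed,
                "tendont2_version": __version__,
            },
            indent=2,
            sort_keys=True,
        )
    )


def fingerprint(obj) -> str:
    """Stable SHA-256 of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()
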