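"""Nuclear run-on calibration and stage-activity deconvolution.

A radioactive nuclear run-on gives, per chromatin sample, a scintillation
count rate (CPM) that is linear in the amount of transcriptionally engaged
polymerase. Serial dilutions of a standard cell line define a calibration
line ``cpm = m * dna_ng + b``; the ratio observed/expected CPM for a sorted
cell fraction then measures its relative transcriptional activity. For mixed
prophase-I fractions with known stage composition (%LZ, %P, %D), per-stage
activities solve the linear system

    observed_i / expected_i = frac_LZ_i * LZ + frac_P_i * P + frac_D_i * D

in least squares. Those activities, combined with sequencing library sizes,
yield the multiplicative normalization constants used to put nascent-seq
coverage tracks from different stages on a common absolute scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tracks import SignalTrack

__all__ = [
    "STAGES",
    "CalibrationError",
    "IdentifiabilityError",
    "StandardCurve",
    "RunOnSample",
    "StageActivities",
    "LibraryNorm",
    "fit_standard_curve",
    "expected_cpm",
    "deconvolve_activities",
    "pure_fraction_activity",
    "normalization_factors",
    "rescale_track",
    "samples_from_table",
]

STAGES = ("LZ", "P", "D")


class CalibrationError(ValueError):
    """Standard-curve fitting or application failed."""


class IdentifiabilityError(ValueError):
    """The composition matrix cannot resolve all stage activities."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS line of best fit for standards: cpm = m * dna_ng + b."""

    m: float
    b: float
    r2: float


@dataclass(frozen=True)
class RunOnSample:
    """One calibrated run-on measurement of a (possibly mixed) cell fraction."""

    sample_id: str
    dna_ng: float
    cpm_observed: float
    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.dna_ng > 0:
            raise ValueError(f"{self.sample_id}: dna_ng must be positive")
        if self.cpm_observed < 0:
            raise ValueError(f"{self.sample_id}: cpm_observed must be >= 0")
        for stage, f in self.composition.items():
            if not 0.0 <= f <= 1.0 + 1e-12:
                raise ValueError(
                    f"{self.sample_id}: composition fraction for {stage} "
                    f"outside [0, 1]: {f}"
                )

    def composition_vector(self, stages: Sequence[str] = STAGES) -> np.ndarray:
        return np.array([self.composition.get(s, 0.0) for s in stages])


@dataclass(frozen=True)
class StageActivities:
    """Relative transcriptional activity per prophase-I stage."""

    activity: Mapping[str, float]
    residual_norm: float = 0.0
    covariance: np.ndarray | None = None

    def ratio(self, stage: str, reference: str) -> float:
        ref = self.activity[reference]
        if ref == 0:
            raise ZeroDivisionError(f"reference stage {reference} has zero activity")
        return self.activity[stage] / ref


@dataclass(frozen=True)
class LibraryNorm:
    """Normalization constants for one stage's sequencing library.

    ``factor`` multiplies bedGraph values: (1/library_size) x activity ratio.
    ``size_factor`` divides raw counts the DESeq2 way: library_size / ratio,
    so counts / size_factor == (counts / library_size) x activity ratio.
    """

    stage: str
    library_size: float
    factor: float
    size_factor: float
    reference_stage: str


def fit_standard_curve(standards: Iterable[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of CPM on DNA input over calibration standards.

    Raises
    ------
    CalibrationError
        Fewer than 2 points, or all DNA inputs identical.
    """
    pts = list(standards)
    if len(pts) < 2:
        raise CalibrationError(f"need >= 2 standards, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise CalibrationError("all standards have identical DNA input")
    res = stats.linregress(x, y)
    return StandardCurve(m=float(res.slope), b=float(res.intercept),
                         r2=float(res.rvalue) ** 2)


def expected_cpm(curve: StandardCurve, dna_ng: float) -> float:
    """Predicted CPM for a sample's DNA input from the standard curve."""
    if not dna_ng > 0:
        raise ValueError(f"dna_ng must be positive, got {dna_ng}")
    pred = curve.m * dna_ng + curve.b
    if pred <= 0:
        raise CalibrationError(
            f"expected CPM {pred:.4g} <= 0 at {dna_ng} ng: sample uncalibratable"
        )
    return pred


def deconvolve_activities(
    samples: Sequence[RunOnSample],
    curve: StandardCurve,
    stages: Sequence[str] = STAGES,
    nonnegative: bool = False,
) -> StageActivities:
    """Solve the composition-weighted linear system for stage activities.

    Row i of the design is sample i's stage-composition fractions; the
    response is observed/expected CPM. Solved by unconstrained ordinary least
    squares (exact when the system is square and consistent); pass
    ``nonnegative=True`` for an NNLS solution instead. Negative unconstrained
    solutions are reported with a warning.
    """
    if len(samples) < len(stages):
        raise IdentifiabilityError(
            f"need >= {len(stages)} samples to resolve {len(stages)} stages, "
            f"got {len(samples)}"
        )
    A = np.vstack([s.composition_vector(stages) for s in samples])
    r = np.array([s.cpm_observed / expected_cpm(curve, s.dna_ng) for s in samples])
    rank = np.linalg.matrix_rank(A)
    if rank < len(stages):
        bad = [
            st for j, st in enumerate(stages)
            if np.linalg.matrix_rank(np.delete(A, j, axis=1)) == rank
        ]
        raise IdentifiabilityError(
            f"composition matrix rank {rank} < {len(stages)}; "
            f"unidentifiable stage(s): {', '.join(bad) or 'all'}"
        )
    if nonnegative:
        a, rnorm = optimize.nnls(A, r)
        resid = rnorm
        cov = None
    else:
        a, res, _, _ = np.linalg.lstsq(A, r, rcond=None)
        resid = float(np.sqrt(res[0])) if res.size else float(
            np.linalg.norm(A @ a - r)
        )
        dof = len(samples) - len(stages)
        if dof > 0:
            sigma2 = resid**2 / dof
            cov = sigma2 * np.linalg.inv(A.T @ A)
        else:
            cov = None
        if np.any(a < 0):
            warnings.warn(
                "deconvolution produced negative activity estimate(s); "
                "consider nonnegative=True",
                stacklevel=2,
            )
    return StageActivities(
        activity=dict(zip(stages, map(float, a))),
        residual_norm=float(resid),
        covariance=cov,
    )


def pure_fraction_activity(sample: RunOnSample, curve: StandardCurve) -> float:
    """Activity of a 100%-pure fraction: observed/expected CPM directly."""
    vec = sample.composition_vector(tuple(sample.composition))
    if not (np.isclose(vec.max(), 1.0) and np.isclose(vec.sum(), 1.0)):
        raise ValueError(
            f"{sample.sample_id}: composition {dict(sample.composition)} is not "
            "a pure fraction"
        )
    return sample.cpm_observed / expected_cpm(curve, sample.dna_ng)


def normalization_factors(
    library_sizes: Mapping[str, float],
    activities: StageActivities,
    reference: str = "LZ",
) -> list[LibraryNorm]:
    """Per-stage bedGraph factors and DESeq2-style size factors.

    factor(stage) = (1 / library_size) x (activity(stage) / activity(reference));
    size_factor(stage) = library_size / (activity(stage) / activity(reference)).
    """
    if reference not in library_sizes:
        raise KeyError(f"reference stage {reference!r} missing from library sizes")
    out = []
    for stage, libsize in library_sizes.items():
        if not libsize > 0:
            raise ValueError(f"library size for {stage} must be positive")
        ratio = activities.ratio(stage, reference)
        if not ratio > 0:
            raise ValueError(f"non-positive activity ratio for stage {stage}")
        out.append(
            LibraryNorm(
                stage=stage,
                library_size=float(libsize),
                factor=ratio / libsize,
                size_factor=libsize / ratio,
                reference_stage=reference,
            )
        )
    return out


def rescale_track(track: SignalTrack, factor: float) -> SignalTrack:
    """Multiply every interval value by ``factor`` (structure unchanged)."""
    if not factor > 0:
        raise ValueError(f"factor must be positive, got {factor}")
    return track.rescaled(factor)


def samples_from_table(df: pd.DataFrame) -> list[RunOnSample]:
    """Build RunOnSample objects from a (sample,dna_ng,cpm,frac_*) table."""
    frac_cols = {c: c.split("_", 1)[1] for c in df.columns if c.startswith("frac_")}
    return [
        RunOnSample(
            sample_id=str(row["sample"]),
            dna_ng=float(row["dna_ng"]),
            cpm_observed=float(row["cpm"]),
            composition={stage: float(row[col]) for col, stage in frac_cols.items()},
        )
        for _, row in df.iterrows()
    ]
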