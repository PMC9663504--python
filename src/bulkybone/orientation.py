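"""Division-orientation statistics for EdU doublets and clone pairs.

A doublet is a pair of daughter-cell positions; its axis reports the
orientation of the cell division.  Orientations are *axial* data — a
division and its reverse are the same event — so every angle is folded
into [0°, 90°] relative to the bone's proximo-distal axis: 0° is a
longitudinal division (elongation), 90° a transversal one (thickening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoubletSet",
    "OrientationSummary",
    "TestResult",
    "doublet_angle",
    "doublet_angles",
    "summarize",
    "compare_groups",
]


@dataclass
class DoubletSet:
    """Point-pair records with group labels and an anatomical axis.

    ``points_a``/``points_b`` are (n,3) mm coordinates; 2-D section data
    are accepted by zero-padding the third coordinate (the axis must
    then lie in-plane).
    """

    points_a: np.ndarray
    points_b: np.ndarray
    groups: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    ids: np.ndarray = None

    def __post_init__(self):
        self.points_a = np.atleast_2d(np.asarray(self.points_a, dtype=float))
        self.points_b = np.atleast_2d(np.asarray(self.points_b, dtype=float))
        if self.points_a.shape[1] == 2:
            self.points_a = np.column_stack([self.points_a, np.zeros(len(self.points_a))])
        if self.points_b.shape[1] == 2:
            self.points_b = np.column_stack([self.points_b, np.zeros(len(self.points_b))])
        if self.points_a.shape != self.points_b.shape:
            raise ValueError("point arrays must have matching shapes")
        self.groups = np.asarray(self.groups)
        if len(self.groups) != len(self.points_a):
            raise ValueError("group labels must match the number of records")
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        self.axis = self.axis / n
        if np.any(np.all(self.points_a == self.points_b, axis=1)):
            raise ValueError("doublet with coincident points")
        if self.ids is None:
            self.ids = np.arange(len(self.points_a))

    def __len__(self):
        return len(self.points_a)

    def angles(self) -> np.ndarray:
        return doublet_angles(self.points_a, self.points_b, self.axis)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "ax": self.points_a[:, 0],
                "ay": self.points_a[:, 1],
                "az": self.points_a[:, 2],
                "bx": self.points_b[:, 0],
                "by": self.points_b[:, 1],
                "bz": self.points_b[:, 2],
                "group": self.groups,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, axis=(0.0, 0.0, 1.0)) -> "DoubletSet":
        req = {"id", "ax", "ay", "az", "bx", "by", "bz", "group"}
        if not req <= set(df.columns):
            raise ValueError(f"doublet table missing columns {sorted(req - set(df.columns))}")
        return cls(
            points_a=df[["ax", "ay", "az"]].to_numpy(float),
            points_b=df[["bx", "by", "bz"]].to_numpy(float),
            groups=df["group"].to_numpy(),
            axis=np.asarray(axis, float),
            ids=df["id"].to_numpy(),
        )


def doublet_angle(point_a, point_b, axis) -> float:
    """Axial angle in degrees in [0, 90] between the doublet direction
    and the bone axis; 0 = longitudinal, 90 = transversal.  Folding via
    the absolute dot product makes (a,b) and (b,a) equivalent."""
    return float(doublet_angles(np.atleast_2d(point_a), np.atleast_2d(point_b), axis)[0])


def doublet_angles(points_a, points_b, axis) -> np.ndarray:
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    d = b - a
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("coincident doublet points")
    cosang = np.abs(d @ ax) / norms
    return np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))


@dataclass(frozen=True)
class OrientationSummary:
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    sd: float
    fraction_transversal: float
    threshold: float

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")
        if not (0 <= self.fraction_transversal <= 1):
            raise ValueError("fraction_transversal outside [0, 1]")


def summarize(angles, threshold: float = 45.0) -> OrientationSummary:
    """Summary statistics of folded angles; ``fraction_transversal`` is
    the share of angles strictly above ``threshold`` (default 45°, the
    longitudinal/transversal midpoint).  Quartiles use linear
    interpolation."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle set")
    if a.min() < 0 or a.max() > 90:
        raise ValueError("angles must lie in [0, 90] degrees")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return OrientationSummary(
        n=int(a.size),
        mean=float(a.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        sd=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        fraction_transversal=float(np.mean(a > threshold)),
        threshold=float(threshold),
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int

    def __post_init__(self):
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    angles_a,
    angles_b,
    method: str = "welch_t",
    n_resamples: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Two-tailed two-group comparison of angle distributions.

    ``welch_t`` is the unequal-variance t test; ``permutation`` shuffles
    group labels ``n_resamples`` times and reports the add-one corrected
    two-sided p-value (b+1)/(m+1) for the difference of means.  Angles
    are bounded, so the permutation test is the distribution-free
    alternative.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "welch_t":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if np.isclose(a.mean(), b.mean()):
                return TestResult(0.0, 1.0, "welch_t", a.size, b.size)
            raise ValueError(
                "zero variance in both groups; Welch t undefined — use permutation"
            )
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return TestResult(float(t), float(p), "welch_t", a.size, b.size)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        na = a.size
        observed = abs(a.mean() - b.mean())
        # argsort of random keys gives independent uniform permutations;
        # chunked so very large resample counts stay within memory
        b_ge = 0
        done = 0
        while done < n_resamples:
            m = min(100_000, n_resamples - done)
            keys = rng.random((m, pooled.size))
            idx = np.argsort(keys, axis=1)
            perm = pooled[idx]
            diffs = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
            b_ge += int(np.count_nonzero(diffs >= observed - 1e-12))
            done += m
        p = (b_ge + 1) / (n_resamples + 1)
        return TestResult(float(observed), float(p), "permutation", a.size, b.size)
    raise ValueError(f"unknown method {method!r}; use 'welch_t' or 'permutation'")
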