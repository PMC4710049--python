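"""Spatial statistics for X/Y transcript segregation.

Kernel-density maps of the spot pattern (truncated Gaussian kernel, window
150 px, SD 25 px), the Y-purity field Y/(X+Y), its histogram with 80%
dominance cutoffs, a label-permutation null (default 100 randomizations over
the fixed spot positions) with signed ±3 SD bin flags and percentile 95%
confidence intervals for the X-dominant / mixed / Y-dominant pixel
proportions, the landmark-based dorsal/ventral partition, and a one-tailed
Welch t-test for regional count ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import stats

from .errors import EmptyFieldError, GeometryError, ParameterError

CATEGORIES = ("x_dominant", "mixed", "y_dominant")


@dataclass(frozen=True)
class KernelSpec:
    """Truncated rotationally symmetric 2-D Gaussian kernel.

    ``window`` is forced odd so the kernel has a center pixel; with
    ``normalized`` the kernel has unit mass, making the density map integrate
    to the spot count (away from edges).
    """

    window: int = 150
    sd: float = 25.0
    normalized: bool = True

    def __post_init__(self):
        if self.sd <= 0:
            raise ParameterError("kernel sd must be > 0")
        if self.window < 1:
            raise ParameterError("kernel window must be >= 1")
        if self.window % 2 == 0:
            object.__setattr__(self, "window", self.window + 1)

    def array(self) -> np.ndarray:
        half = self.window // 2
        ax = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-(ax**2) / (2.0 * self.sd**2))
        k = np.outer(g, g)
        if self.normalized:
            k = k / k.sum()
        return k


@dataclass
class DensityField:
    maps: dict[str, np.ndarray]
    kernel: KernelSpec
    spot_counts: dict[str, int]

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.maps[gene]


@dataclass
class PurityField:
    """Y-fraction field; NaN marks pixels masked as background (X+Y < eps)."""

    purity: np.ndarray
    eps: float

    def unmasked(self) -> np.ndarray:
        vals = self.purity[np.isfinite(self.purity)]
        return vals


@dataclass
class PurityHistogram:
    bin_edges: np.ndarray
    frequencies: np.ndarray
    cutoff: float
    proportions: dict[str, float]
    n_pixels: int


@dataclass
class PermutationSummary:
    """Observed-vs-randomized summary of the label-permutation null."""

    n_rand: int
    seed: int
    cutoff: float
    eps: float
    bin_edges: np.ndarray
    observed_freq: np.ndarray
    rand_mean: np.ndarray
    rand_sd: np.ndarray
    flags: np.ndarray  # per bin: +1 over-represented (>+3 SD), -1 under, 0 none
    observed_props: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    outside_ci: dict[str, bool]
    label_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_rand": self.n_rand,
            "seed": self.seed,
            "cutoff": self.cutoff,
            "eps": self.eps,
            "bin_edges": self.bin_edges.tolist(),
            "observed_freq": self.observed_freq.tolist(),
            "rand_mean": self.rand_mean.tolist(),
            "rand_sd": self.rand_sd.tolist(),
            "flags": self.flags.tolist(),
            "observed_props": self.observed_props,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "outside_ci": self.outside_ci,
            "label_counts": self.label_counts,
        }


@dataclass
class RegionPartition:
    """Dorsal/ventral split of the tissue mask by a landmark-derived border."""

    region: np.ndarray  # 0 outside tissue, 1 dorsal, 2 ventral
    border: tuple[float, float]  # (intercept row at col 0, slope row/col)

    def border_row(self, col) -> np.ndarray:
        b0, b1 = self.border
        return b0 + b1 * np.asarray(col, dtype=float)


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


class _FFTConvolver:
    """Same-mode 2-D convolution with a cached kernel spectrum.

    The kernel FFT is computed once per (image shape, kernel) pair so the
    permutation loop pays only one forward/backward transform per
    randomization.
    """

    def __init__(self, shape: tuple[int, int], kernel: np.ndarray):
        self.shape = shape
        self.kshape = kernel.shape
        self.fast = (
            sp_fft.next_fast_len(shape[0] + kernel.shape[0] - 1),
            sp_fft.next_fast_len(shape[1] + kernel.shape[1] - 1),
        )
        self.fkernel = sp_fft.rfft2(kernel, s=self.fast)

    def convolve(self, image: np.ndarray) -> np.ndarray:
        full = sp_fft.irfft2(sp_fft.rfft2(image, s=self.fast) * self.fkernel, s=self.fast)
        r0, c0 = self.kshape[0] // 2, self.kshape[1] // 2
        out = full[r0 : r0 + self.shape[0], c0 : c0 + self.shape[1]]
        return np.maximum(out, 0.0)


def _count_image(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    np.add.at(img, (rows, cols), 1.0)
    return img


class _StampConvolver:
    """Density by direct kernel stamping at spot positions.

    Exact (pure float64 adds) and faster than the FFT route for the moderate
    spot counts of a single section, so the permutation loop uses it.
    """

    def __init__(self, shape: tuple[int, int], kernel: np.ndarray):
        self.shape = shape
        self.kernel = kernel
        self.half = (kernel.shape[0] // 2, kernel.shape[1] // 2)
        self._pad = np.zeros((shape[0] + 2 * self.half[0], shape[1] + 2 * self.half[1]))

    def density(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel.shape
        pad = self._pad
        pad[:] = 0.0
        for r, c in zip(rows, cols):
            pad[r : r + kh, c : c + kw] += self.kernel
        h0, h1 = self.half
        return pad[h0 : h0 + self.shape[0], h1 : h1 + self.shape[1]].copy()


def density_map(
    spots: pd.DataFrame,
    shape: tuple[int, int],
    kernel: KernelSpec | None = None,
    genes: Sequence[str] | None = None,
) -> DensityField:
    """Per-gene KDE maps: spot count images convolved with the Gaussian kernel.

    Each signal contributes one pixel to its gene's count image (coincident
    signals accumulate), so the map is linear in the spot set and, with a
    normalized kernel, integrates to the spot count for interior spots. An
    empty spot set gives an all-zero map.
    """
    kernel = kernel or KernelSpec()
    if genes is None:
        genes = sorted(spots["gene"].unique())
    r = spots["row"].to_numpy(dtype=int)
    c = spots["col"].to_numpy(dtype=int)
    if len(r) and (
        (r < 0).any() or (r >= shape[0]).any() or (c < 0).any() or (c >= shape[1]).any()
    ):
        raise ParameterError("spot coordinates outside the requested shape")
    conv = _FFTConvolver(shape, kernel.array())
    maps: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for gene in genes:
        sel = (spots["gene"] == gene).to_numpy()
        counts[gene] = int(sel.sum())
        maps[gene] = conv.convolve(_count_image(r[sel], c[sel], shape))
    return DensityField(maps=maps, kernel=kernel, spot_counts=counts)


def default_eps(total_density: np.ndarray) -> float:
    """Background-masking floor: 1e-3 x mean positive total density."""
    positive = total_density[total_density > 0]
    if positive.size == 0:
        return np.inf
    return 1e-3 * float(positive.mean())


def purity_field(
    density_x: np.ndarray, density_y: np.ndarray, eps: float | None = None
) -> PurityField:
    """Y-purity Y/(X+Y), masked (NaN) where the total density is below eps."""
    if density_x.shape != density_y.shape:
        raise ParameterError("density maps must share one shape")
    if (density_x < 0).any() or (density_y < 0).any():
        raise ParameterError("densities must be non-negative")
    total = density_x + density_y
    if eps is None:
        eps = default_eps(total)
    purity = np.full(density_x.shape, np.nan)
    ok = total >= eps
    with np.errstate(invalid="ignore"):
        purity[ok] = density_y[ok] / total[ok]
    return PurityField(purity=purity, eps=float(eps))


def _bin_index(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin purity values on [0, 1] (right edge inclusive in the last bin)."""
    idx = np.floor(values * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _histogram_and_props(
    values: np.ndarray, n_bins: int, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    freq = np.bincount(_bin_index(values, n_bins), minlength=n_bins).astype(float)
    n = len(values)
    props = np.array(
        [
            (values <= 1.0 - cutoff).sum() / n,
            np.logical_and(values > 1.0 - cutoff, values < cutoff).sum() / n,
            (values >= cutoff).sum() / n,
        ]
    )
    return freq, props


def purity_histogram(
    field: PurityField, n_bins: int = 50, cutoff: float = 0.8
) -> PurityHistogram:
    """Equal-width histogram of unmasked purity values with dominance classes.

    A pixel is X-dominant at purity <= 1-cutoff, Y-dominant at >= cutoff
    (boundary inclusive on the dominant side), mixed otherwise.
    """
    if not 0.5 < cutoff <= 1.0:
        raise ParameterError("dominance cutoff must lie in (0.5, 1]")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    values = field.unmasked()
    if values.size == 0:
        raise EmptyFieldError("purity field has no unmasked pixels")
    freq, props = _histogram_and_props(values, n_bins, cutoff)
    return PurityHistogram(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        frequencies=freq,
        cutoff=cutoff,
        proportions=dict(zip(CATEGORIES, props.tolist())),
        n_pixels=int(values.size),
    )


def permutation_null(
    spots: pd.DataFrame,
    shape: tuple[int, int],
    kernel: KernelSpec | None = None,
    x_gene: str = "X",
    y_gene: str = "Y",
    eps: float | None = None,
    n_bins: int = 50,
    cutoff: float = 0.8,
    n_rand: int = 100,
    seed: int = 0,
) -> PermutationSummary:
    """Label-permutation null for spatial X/Y segregation.

    Each randomization reassigns the X/Y labels uniformly over the fixed spot
    positions, preserving the label counts exactly, and recomputes the purity
    histogram and dominance-category proportions. Bins where the observed
    frequency deviates from the randomized mean by more than 3 randomized SDs
    are flagged (signed); the three category proportions get percentile 95%
    confidence intervals over the randomizations.

    The total density X+Y — and therefore the background mask — is invariant
    under label permutation, so observed and randomized purities are compared
    on identical pixels.
    """
    kernel = kernel or KernelSpec()
    if n_rand < 2:
        raise ParameterError("n_rand must be >= 2 to estimate an SD")
    sub = spots[spots["gene"].isin([x_gene, y_gene])].reset_index(drop=True)
    if len(sub) == 0:
        raise ParameterError("no spots with the requested labels")
    r = sub["row"].to_numpy(dtype=int)
    c = sub["col"].to_numpy(dtype=int)
    is_y = (sub["gene"] == y_gene).to_numpy()
    n_spots, n_y = len(sub), int(is_y.sum())

    conv = _StampConvolver(shape, kernel.array())
    total_density = conv.density(r, c)
    if eps is None:
        eps = default_eps(total_density)
    mask = total_density >= eps
    if not mask.any():
        raise EmptyFieldError("all pixels masked at the requested eps")
    total_on = total_density[mask]

    def y_purity(y_rows, y_cols):
        dy = conv.density(y_rows, y_cols)
        return np.clip(dy[mask] / total_on, 0.0, 1.0)

    obs_freq, obs_props = _histogram_and_props(y_purity(r[is_y], c[is_y]), n_bins, cutoff)

    rand_freq = np.empty((n_rand, n_bins))
    rand_props = np.empty((n_rand, 3))
    for i in range(n_rand):
        rng = np.random.default_rng([seed, i])
        perm = rng.permutation(n_spots)
        y_idx = perm[:n_y]
        assert len(y_idx) == n_y  # exchangeability: label multiset preserved
        rand_freq[i], rand_props[i] = _histogram_and_props(
            y_purity(r[y_idx], c[y_idx]), n_bins, cutoff
        )

    mean = rand_freq.mean(axis=0)
    sd = rand_freq.std(axis=0, ddof=1)
    diff = obs_freq - mean
    flags = np.zeros(n_bins, dtype=np.int8)
    flags[diff > 3.0 * sd] = 1
    flags[diff < -3.0 * sd] = -1
    flags[diff == 0] = 0

    # conservative order-statistic percentiles: a linearly interpolated
    # interval from 100 randomizations is too narrow and over-rejects an
    # exchangeable observation (~7% instead of the nominal 5%)
    lo = np.percentile(rand_props, 2.5, axis=0, method="lower")
    hi = np.percentile(rand_props, 97.5, axis=0, method="higher")
    outside = (obs_props < lo) | (obs_props > hi)
    return PermutationSummary(
        n_rand=n_rand,
        seed=seed,
        cutoff=cutoff,
        eps=float(eps),
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        observed_freq=obs_freq,
        rand_mean=mean,
        rand_sd=sd,
        flags=flags,
        observed_props=dict(zip(CATEGORIES, obs_props.tolist())),
        ci_low=dict(zip(CATEGORIES, lo.tolist())),
        ci_high=dict(zip(CATEGORIES, hi.tolist())),
        outside_ci=dict(zip(CATEGORIES, outside.tolist())),
        label_counts={x_gene: n_spots - n_y, y_gene: n_y},
    )


def flag_pixels(
    field: PurityField, bin_edges: np.ndarray, flags: np.ndarray, sign: int = 1
) -> np.ndarray:
    """Mark unmasked pixels whose purity falls in a flagged bin.

    ``sign=+1`` selects over-represented (> +3 SD) bins, ``-1`` the
    under-represented ones.
    """
    n_bins = len(bin_edges) - 1
    out = np.zeros(field.purity.shape, dtype=bool)
    ok = np.isfinite(field.purity)
    if not ok.any() or not (flags == sign).any():
        return out
    idx = _bin_index(field.purity[ok], n_bins)
    out[ok] = (flags == sign)[idx]
    return out


def dorsoventral_partition(
    mask: np.ndarray,
    left_pair: Sequence[Sequence[float]],
    right_pair: Sequence[Sequence[float]],
) -> RegionPartition:
    """Split the tissue by the line through the midpoints of two landmark pairs.

    Each pair spans dorsal-to-ventral on one side of the section; the border
    line passes through the two midpoints. Pixels above the line (smaller row)
    are dorsal, pixels on or below it ventral.
    """
    left = np.asarray(left_pair, dtype=float)
    right = np.asarray(right_pair, dtype=float)
    for name, pair in (("left", left), ("right", right)):
        if pair.shape != (2, 2):
            raise GeometryError(f"{name} landmark pair must be two (row, col) points")
        if np.allclose(pair[0], pair[1]):
            raise GeometryError(f"{name} landmark pair is degenerate (coincident points)")
        for r, c in pair:
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
                raise GeometryError(f"{name} landmark ({r}, {c}) lies outside the tissue mask")
    ml = left.mean(axis=0)
    mr = right.mean(axis=0)
    if abs(mr[1] - ml[1]) < 1e-9:
        raise GeometryError("landmark midpoints share a column; border line undefined")
    slope = (mr[0] - ml[0]) / (mr[1] - ml[1])
    intercept = ml[0] - slope * ml[1]
    rows, cols = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    border_rows = intercept + slope * cols
    region = np.zeros(mask.shape, dtype=np.int8)
    region[mask & (rows < border_rows)] = 1
    region[mask & (rows >= border_rows)] = 2
    return RegionPartition(region=region, border=(float(intercept), float(slope)))


def region_ratio(
    spots: pd.DataFrame, partition: RegionPartition, x_gene: str, y_gene: str
) -> dict[str, dict[str, float]]:
    """X:Y count ratio per region; NaN ratio flags a zero Y denominator.

    Spots outside the tissue mask are ignored. A region with no Y spots has an
    undefined ratio and should be excluded from downstream testing.
    """
    out: dict[str, dict[str, float]] = {}
    r = spots["row"].to_numpy(dtype=int)
    c = spots["col"].to_numpy(dtype=int)
    reg = partition.region[r, c] if len(spots) else np.zeros(0, dtype=np.int8)
    for name, code in (("dorsal", 1), ("ventral", 2)):
        sel = reg == code
        nx = int(((spots["gene"] == x_gene).to_numpy() & sel).sum())
        ny = int(((spots["gene"] == y_gene).to_numpy() & sel).sum())
        out[name] = {
            "x_count": nx,
            "y_count": ny,
            "ratio": (nx / ny) if ny > 0 else float("nan"),
        }
    return out


def welch_one_tailed(
    group_a: Sequence[float], group_b: Sequence[float], alternative: str = "a_greater"
) -> WelchResult:
    """One-tailed two-sample t-test assuming unequal variances.

    ``alternative`` is ``"a_greater"`` (mean(a) > mean(b)) or ``"b_greater"``.
    Uses the Welch statistic with Welch–Satterthwaite degrees of freedom. Two
    groups with zero pooled variance are degenerate and reported as such.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if alternative not in ("a_greater", "b_greater"):
        raise ParameterError("alternative must be 'a_greater' or 'b_greater'")
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("groups must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    delta = a.mean() - b.mean()
    if alternative == "b_greater":
        delta = -delta
    if se2 == 0:
        if delta == 0:
            return WelchResult(t=0.0, df=float("nan"), p=0.5, degenerate=True)
        return WelchResult(
            t=float(np.sign(delta)) * float("inf"),
            df=float("nan"),
            p=0.0 if delta > 0 else 1.0,
            degenerate=True,
        )
    t = delta / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(stats.t.sf(t, df))
    return WelchResult(t=float(t), df=float(df), p=p)
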