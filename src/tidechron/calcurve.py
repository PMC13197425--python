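"""Radiocarbon calibration curves and single-date calibration.

A calibration curve tabulates the conventional radiocarbon age mu(theta)
and its one-sigma uncertainty sigma(theta) as a function of calendar age
theta in cal BP (calendar years before AD 1950).  Curves are read from
the plain-text ``.14c`` dialect used by the IntCal family of curves:
``#``-prefixed comment lines followed by comma-separated rows of
``calBP, 14C age BP, error`` in descending calendar age.

The module supports the three curve manipulations needed for
marine-influenced consumers:

* shifting a marine curve by a local reservoir offset (Delta-R),
* convex mixing of a terrestrial and a (shifted) marine curve in
  proportion to a consumer's marine diet fraction, and
* calibrating a single determination against any such curve on a
  one-year calendar grid.

All internal calendar arithmetic is in cal BP; ``AD = 1950 - calBP``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np

__all__ = [
    "CurveError",
    "CurveParseError",
    "DegenerateCurveError",
    "OutOfRangeError",
    "CalibrationCurve",
    "MixedCurve",
    "ReservoirOffset",
    "RadiocarbonDetermination",
    "CalendarDensity",
    "parse_curve_file",
    "write_curve_file",
    "load_bundled_curve",
    "curve_lookup",
    "shift_marine",
    "mix_curves",
    "calibrate_single",
]

#: default calendar window (cal BP) intersected with the curve span
DEFAULT_WINDOW = (-55.0, 5000.0)

#: likelihood values below this fraction of the maximum are trimmed
LIKELIHOOD_FLOOR = 1e-12


class CurveError(ValueError):
    """Base class for calibration-curve problems."""


class CurveParseError(CurveError):
    """A curve file row could not be parsed (carries the line number)."""


class DegenerateCurveError(CurveError):
    """Fewer than two data rows: not a usable curve."""


class OutOfRangeError(CurveError):
    """A calendar age outside the tabulated span was requested."""


@dataclass(frozen=True)
class RadiocarbonDetermination:
    """One laboratory radiocarbon measurement.

    Parameters
    ----------
    lab_code : str
        Laboratory identifier, e.g. ``"UCIAMS-270835"``.
    age : float
        Conventional radiocarbon age in 14C years BP.
    sigma : float
        One-sigma measurement error in 14C years; must be positive.
    material : str
        Free-text material class (``"human bone"``, ``"charcoal"``, ...).
    tissue : str or None
        Sampled tissue for human material (``"second_molar"``, ...).
    context : str or None
        Link to an archaeological context / model event.
    """

    lab_code: str
    age: float
    sigma: float
    material: str = "unknown"
    tissue: str | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"determination {self.lab_code}: sigma must be > 0")


@dataclass(frozen=True)
class ReservoirOffset:
    """Local marine reservoir offset Delta-R in 14C years.

    ``fixed`` mode carries a point estimate with uncertainty that is
    folded into the curve error in quadrature; ``free`` mode carries
    uniform prior bounds and is sampled as a model parameter by the
    joint chronological model.
    """

    mode: str = "fixed"  # "fixed" | "free"
    mean: float = 0.0
    sd: float = 0.0
    lower: float = -600.0
    upper: float = 200.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "free"):
            raise ValueError(f"unknown ReservoirOffset mode {self.mode!r}")
        if self.mode == "fixed" and self.sd < 0:
            raise ValueError("fixed-mode ReservoirOffset sd must be >= 0")
        if self.mode == "free" and not self.lower < self.upper:
            raise ValueError("free-mode ReservoirOffset requires lower < upper")


class CalibrationCurve:
    """A tabulated calendar-age -> 14C-age map with 1-sigma errors.

    The grid is stored in file order (descending cal BP) and exposed as
    a function of calendar age through linear interpolation of both the
    mean and the error.
    """

    def __init__(
        self,
        name: str,
        cal_bp: Sequence[float],
        c14_age: Sequence[float],
        sigma: Sequence[float],
        kind: str = "terrestrial",
    ) -> None:
        if kind not in ("terrestrial", "marine"):
            raise ValueError(f"curve kind must be terrestrial|marine, got {kind!r}")
        cal = np.asarray(cal_bp, dtype=float)
        mu = np.asarray(c14_age, dtype=float)
        sig = np.asarray(sigma, dtype=float)
        if cal.size < 2:
            raise DegenerateCurveError(
                f"curve {name!r} has {cal.size} data rows; need at least 2"
            )
        d = np.diff(cal)
        if np.all(d < 0):
            pass  # canonical descending order
        elif np.all(d > 0):
            cal, mu, sig = cal[::-1], mu[::-1], sig[::-1]
        else:
            raise CurveError(f"curve {name!r}: calendar ages are not strictly monotone")
        if np.any(sig <= 0):
            raise CurveError(f"curve {name!r}: sigma must be > 0 at every grid point")
        self.name = name
        self.kind = kind
        self.cal_bp = cal  # descending
        self.c14_age = mu
        self.sigma = sig
        # ascending views for numpy interpolation
        self._cal_asc = cal[::-1]
        self._mu_asc = mu[::-1]
        self._sig_asc = sig[::-1]

    # -- span ---------------------------------------------------------------

    @property
    def span(self) -> tuple[float, float]:
        """(youngest, oldest) tabulated calendar age in cal BP."""
        return float(self._cal_asc[0]), float(self._cal_asc[-1])

    def _check_range(self, t: np.ndarray) -> None:
        lo, hi = self.span
        t = np.atleast_1d(t)
        if np.any(t < lo) or np.any(t > hi):
            raise OutOfRangeError(
                f"calendar age outside curve {self.name!r} span [{lo}, {hi}] cal BP"
            )

    # -- evaluation ---------------------------------------------------------

    def mu(self, t):
        """Interpolated 14C age at calendar age ``t`` (cal BP)."""
        self._check_range(np.asarray(t, dtype=float))
        return np.interp(t, self._cal_asc, self._mu_asc)

    def sigma_at(self, t):
        """Interpolated 1-sigma curve error at calendar age ``t``."""
        self._check_range(np.asarray(t, dtype=float))
        return np.interp(t, self._cal_asc, self._sig_asc)

    def __len__(self) -> int:
        return int(self.cal_bp.size)

    def __repr__(self) -> str:
        lo, hi = self.span
        return (
            f"CalibrationCurve({self.name!r}, kind={self.kind!r}, "
            f"n={len(self)}, span=({lo:g}, {hi:g}) cal BP)"
        )


class MixedCurve:
    """Convex combination of a terrestrial and a marine curve.

    For marine diet fraction ``m``::

        mu_mix(t)    = (1 - m) * mu_terr(t) + m * mu_marine(t)
        sigma_mix(t) = sqrt((1 - m)^2 sigma_terr(t)^2 + m^2 sigma_marine(t)^2)

    The marine component is expected to be already shifted by the local
    reservoir offset (see :func:`shift_marine`).
    """

    def __init__(self, terrestrial: CalibrationCurve, marine: CalibrationCurve, m: float):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"marine fraction m must lie in [0, 1], got {m}")
        self.terrestrial = terrestrial
        self.marine = marine
        self.m = float(m)
        self.name = f"mix({terrestrial.name},{marine.name},m={m:g})"
        self.kind = "mixed"

    @property
    def span(self) -> tuple[float, float]:
        lo_t, hi_t = self.terrestrial.span
        lo_m, hi_m = self.marine.span
        lo, hi = max(lo_t, lo_m), min(hi_t, hi_m)
        if lo >= hi:
            raise CurveError("component curves have no overlapping calendar span")
        return lo, hi

    def mu(self, t):
        m = self.m
        return (1.0 - m) * self.terrestrial.mu(t) + m * self.marine.mu(t)

    def sigma_at(self, t):
        m = self.m
        return np.sqrt(
            (1.0 - m) ** 2 * np.asarray(self.terrestrial.sigma_at(t)) ** 2
            + m**2 * np.asarray(self.marine.sigma_at(t)) ** 2
        )


#: anything calibrate_single accepts
CurveLike = Union[CalibrationCurve, MixedCurve]


@dataclass
class CalendarDensity:
    """A normalized probability mass function on a 1-year calendar grid."""

    grid: np.ndarray  # ascending cal BP, 1-year step
    weights: np.ndarray  # nonnegative, sums to 1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.grid.shape != self.weights.shape:
            raise ValueError("grid and weights must have the same shape")
        total = self.weights.sum()
        if not total > 0:
            raise ValueError("density has no mass")
        self.weights = self.weights / total

    @property
    def grid_ad(self) -> np.ndarray:
        """The grid on the AD scale (AD = 1950 - calBP)."""
        return 1950.0 - self.grid

    def quantile_bp(self, q) -> np.ndarray:
        """Quantiles of calendar age (cal BP); q in [0,1], quantiles of the
        *older-to-younger* cumulative ordering so q=0.5 is the median."""
        cdf = np.cumsum(self.weights)
        return np.interp(np.atleast_1d(q), cdf, self.grid)

    def median_bp(self) -> float:
        return float(self.quantile_bp(0.5)[0])

    def median_ad(self) -> float:
        return 1950.0 - self.median_bp()

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw calendar ages (cal BP) from the pmf, jittered uniformly
        within each one-year bin."""
        idx = rng.choice(self.grid.size, size=size, p=self.weights)
        return self.grid[idx] + rng.uniform(-0.5, 0.5, size=size)


# ---------------------------------------------------------------------------
# parsing / writing


def parse_curve_file(path: Union[str, Path, IO[str]], name: str, kind: str) -> CalibrationCurve:
    """Parse an IntCal-dialect ``.14c`` file into a :class:`CalibrationCurve`.

    Lines starting with ``#`` are comments; data rows are comma-separated
    ``calBP, 14C age BP, 1-sigma error``.  Raises
    :class:`CurveParseError` naming the offending line on malformed rows
    and :class:`DegenerateCurveError` when fewer than two data rows are
    present.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
        src = getattr(path, "name", "<stream>")
    else:
        src = str(path)
        lines = Path(path).read_text().splitlines()

    cal, mu, sig = [], [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3:
            raise CurveParseError(
                f"{src}: line {lineno}: expected 'calBP, 14C age, error', got {raw!r}"
            )
        try:
            cal.append(float(parts[0]))
            mu.append(float(parts[1]))
            sig.append(float(parts[2]))
        except ValueError as exc:
            raise CurveParseError(f"{src}: line {lineno}: non-numeric field in {raw!r}") from exc
    if len(cal) < 2:
        raise DegenerateCurveError(f"{src}: found {len(cal)} data rows; need at least 2")
    return CalibrationCurve(name, cal, mu, sig, kind=kind)


def write_curve_file(curve: CalibrationCurve, path: Union[str, Path], comments: Iterable[str] = ()) -> None:
    """Write a curve in the same ``.14c`` dialect (descending cal BP).

    ``write(parse(f))`` reproduces the data rows of ``f`` exactly
    (comments and whitespace aside).
    """
    out = []
    for c in comments:
        out.append(f"# {c}")
    for t, m, s in zip(curve.cal_bp, curve.c14_age, curve.sigma):
        out.append(f"{t:g},{m:g},{s:g}")
    Path(path).write_text("\n".join(out) + "\n")


_BUNDLED = {
    "shcal20": ("shcal20_synthetic.14c", "terrestrial"),
    "marine20": ("marine20_synthetic.14c", "marine"),
}


def load_bundled_curve(key: str) -> CalibrationCurve:
    """Load one of the bundled reference curves by key.

    Keys are ``"shcal20"`` (Southern Hemisphere terrestrial) and
    ``"marine20"`` (global surface ocean).  The bundled files are
    *synthetic stand-ins*: smooth, monotone approximations of the
    published curves built from generic Holocene anchor points (see
    ``tidechron/data``), adequate for method development and testing but
    not for publication-grade calibration.  Substitute the genuine
    IntCal-distribution files via :func:`parse_curve_file` for real
    analyses.
    """
    try:
        fname, kind = _BUNDLED[key.lower()]
    except KeyError:
        raise KeyError(f"no bundled curve {key!r}; options: {sorted(_BUNDLED)}") from None
    from importlib.resources import files

    resource = files("tidechron.data").joinpath(fname)
    with resource.open("r") as fh:
        return parse_curve_file(fh, name=key.upper().replace("CAL", "Cal").replace("MARINE", "Marine"), kind=kind)


# ---------------------------------------------------------------------------
# operations


def curve_lookup(curve: CurveLike, t: float) -> tuple[float, float]:
    """Return ``(mu, sigma)`` at calendar age ``t`` by linear interpolation."""
    return float(curve.mu(t)), float(curve.sigma_at(t))


def shift_marine(curve: CalibrationCurve, offset: ReservoirOffset) -> CalibrationCurve:
    """Apply a fixed-mode reservoir offset to a marine curve.

    ``mu' = mu + offset.mean`` at every node and the offset uncertainty
    is folded into the curve error in quadrature,
    ``sigma' = sqrt(sigma^2 + offset.sd^2)``.
    """
    if curve.kind != "marine":
        raise CurveError(f"shift_marine requires a marine curve, got kind {curve.kind!r}")
    if offset.mode != "fixed":
        raise ValueError("shift_marine takes a fixed-mode ReservoirOffset; free-mode "
                         "offsets are sampled inside the joint model")
    return CalibrationCurve(
        name=f"{curve.name}+dR({offset.mean:g})",
        cal_bp=curve.cal_bp,
        c14_age=curve.c14_age + offset.mean,
        sigma=np.sqrt(curve.sigma**2 + offset.sd**2),
        kind="marine",
    )


def mix_curves(terrestrial: CalibrationCurve, marine_shifted: CalibrationCurve, m: float) -> MixedCurve:
    """Convex mixture of a terrestrial and a reservoir-shifted marine curve."""
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"marine fraction m must lie in [0, 1], got {m}")
    return MixedCurve(terrestrial, marine_shifted, m)


def calibrate_single(
    det: RadiocarbonDetermination,
    curve: CurveLike,
    window: tuple[float, float] | None = None,
) -> CalendarDensity:
    """Calibrate one determination against a (possibly mixed) curve.

    The posterior under a uniform calendar prior is::

        p(theta) ~ Normal(det.age; mu(theta), det.sigma^2 + sigma_curve(theta)^2)

    evaluated on a one-year grid over the curve span intersected with
    ``window`` (default [-55, 5000] cal BP), normalized to sum to one,
    and trimmed to the region where the likelihood exceeds ``1e-12`` of
    its maximum.
    """
    lo_c, hi_c = curve.span
    lo_w, hi_w = window if window is not None else DEFAULT_WINDOW
    lo, hi = max(lo_c, lo_w), min(hi_c, hi_w)
    if lo >= hi:
        raise CurveError("calibration window does not intersect the curve span")
    grid = np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float)
    mu = np.asarray(curve.mu(grid), dtype=float)
    var = det.sigma**2 + np.asarray(curve.sigma_at(grid), dtype=float) ** 2
    # the measurement must be reachable somewhere on the window: an
    # everywhere-extreme standardized residual means the window (or the
    # curve) does not cover this determination
    z = np.abs(det.age - mu) / np.sqrt(var)
    if z.min() > 8.0:
        raise CurveError(
            "likelihood is negligible everywhere on the window "
            f"(best fit {z.min():.1f} sigma away); extend the calendar window"
        )
    # log-likelihood, stabilized before exponentiation
    logl = -0.5 * (det.age - mu) ** 2 / var - 0.5 * np.log(var)
    logl -= logl.max()
    lik = np.exp(logl)
    keep = lik > LIKELIHOOD_FLOOR
    # contiguous trim spanning all retained points keeps the grid regular
    idx = np.nonzero(keep)[0]
    sl = slice(idx[0], idx[-1] + 1)
    return CalendarDensity(grid[sl], lik[sl])
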