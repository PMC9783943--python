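"""Four classical tests of Rapoport's rule on species elevational ranges.

Rapoport's rule predicts that species range sizes increase toward higher
elevations.  The four band/species-based tests differ in how species are
assigned to elevation bands:

* **Stevens**: a species contributes its range size to *every* band its
  range overlaps; per-band mean range is regressed on band mid-elevation.
* **Pagel**: each species contributes only to the band containing its
  *upper* range limit.
* **Rohde (mid-point)**: each species contributes only to the band
  containing its range *midpoint*; besides the linear fit, a quadratic
  (parabolic) fit is reported because a bounded domain alone pushes this
  profile toward an interior maximum (the mid-domain effect).
* **Cross-species**: one point per species, range size against range
  midpoint, no banding.

Band conventions (half-open, last band closed; empty bands excluded from
fits rather than imputed) follow :mod:`elevdiv.occurrence_io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .occurrence_io import ElevationBandSpec, SpeciesRange, assign_band

__all__ = [
    "RegressionResult",
    "MethodResult",
    "fit_linear",
    "fit_quadratic",
    "stevens_method",
    "pagel_method",
    "rohde_midpoint_method",
    "cross_species_method",
    "run_all_methods",
]

METHODS = ("stevens", "pagel", "rohde_midpoint", "cross_species")


@dataclass(frozen=True)
class RegressionResult:
    """Least-squares fit summary (degree 1 or 2).

    For degree 1, ``slope`` is the fitted slope and ``r_squared ==
    pearson_r**2``.  For degree 2, ``coefficients`` holds (a, b, c) of
    ``a x^2 + b x + c``, ``slope`` is the leading coefficient a, and the
    p-value is the overall F-test of the quadratic model.
    """

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n_points: int
    degree: int
    coefficients: tuple[float, ...]

    @property
    def vertex_x(self) -> float:
        """Abscissa of the parabola vertex (degree-2 fits only)."""
        if self.degree != 2:
            raise ValueError("vertex is defined for quadratic fits only")
        a, b, _ = self.coefficients
        if a == 0:
            return float("nan")
        return -b / (2.0 * a)


@dataclass
class MethodResult:
    """Outcome of one Rapoport test: the fitted points and the verdict.

    ``supports_rapoport`` is 'positive' when the linear slope is positive
    and significant at ``alpha``, 'negative' for a significant negative
    slope, else 'inconclusive'.  For the mid-point method ``unimodal``
    records whether the quadratic fit has a negative leading coefficient
    with an interior vertex.
    """

    method: str
    x: list[float]
    y: list[float]
    species_counts: list[int]
    fit: RegressionResult
    quadratic_fit: RegressionResult | None = None
    unimodal: bool | None = None
    supports_rapoport: str = "inconclusive"
    band_indices: list[int] | None = None
    excluded_bands: list[int] | None = None


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares with Pearson r and a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError(f"linear fit needs at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        # flat response: zero slope, no linear association
        return RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            pearson_r=0.0,
            p_value=1.0,
            n_points=int(x.size),
            degree=1,
            coefficients=(0.0, float(y[0])),
        )
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r * r,
        pearson_r=r,
        p_value=float(res.pvalue),
        n_points=int(x.size),
        degree=1,
        coefficients=(float(res.slope), float(res.intercept)),
    )


def fit_quadratic(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Degree-2 least squares; R^2 from residuals, p from the overall F-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 4:
        raise ValueError(f"quadratic fit needs at least 4 points, got {x.size}")
    if np.unique(x).size < 3:
        raise ValueError("quadratic fit needs at least 3 distinct x values")
    a, b, c = np.polyfit(x, y, 2)
    yhat = np.polyval([a, b, c], x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    n = int(x.size)
    if r2 >= 1.0:
        p = 0.0
    else:
        f = (r2 / 2.0) / ((1.0 - r2) / (n - 3))
        p = float(stats.f.sf(f, 2, n - 3))
    pear = float(stats.pearsonr(x, y).statistic) if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        slope=float(a),
        intercept=float(c),
        r_squared=r2,
        pearson_r=pear,
        p_value=p,
        n_points=n,
        degree=2,
        coefficients=(float(a), float(b), float(c)),
    )


# ---------------------------------------------------------------------------
# Band assignment helpers


def _band_members_overlap(
    ranges: Sequence[SpeciesRange], bands: ElevationBandSpec
) -> list[list[SpeciesRange]]:
    """Stevens rule: a species belongs to every band its range intersects.

    With half-open bands [lo, hi): member iff min_elev < hi and
    max_elev >= lo; the last band is closed so min_elev <= hi counts.
    """
    edges = bands.edges()
    members: list[list[SpeciesRange]] = [[] for _ in range(bands.n_bands)]
    for sp in ranges:
        for i in range(bands.n_bands):
            lo, hi = edges[i], edges[i + 1]
            last = i == bands.n_bands - 1
            upper_ok = sp.min_elev_m <= hi if last else sp.min_elev_m < hi
            if upper_ok and sp.max_elev_m >= lo:
                members[i].append(sp)
    return members


def _band_members_point(
    ranges: Sequence[SpeciesRange], bands: ElevationBandSpec, attr: str
) -> list[list[SpeciesRange]]:
    """Pagel/Rohde rule: each species in exactly one band, by a point attribute."""
    members: list[list[SpeciesRange]] = [[] for _ in range(bands.n_bands)]
    for sp in ranges:
        members[assign_band(getattr(sp, attr), bands)].append(sp)
    return members


def _banded_result(
    method: str,
    members: list[list[SpeciesRange]],
    bands: ElevationBandSpec,
    alpha: float,
    with_quadratic: bool = False,
) -> MethodResult:
    mids = bands.midpoints()
    occupied = [i for i, m in enumerate(members) if m]
    excluded = [i for i, m in enumerate(members) if not m]
    if len(occupied) < 3:
        raise ValueError(
            f"{method}: only {len(occupied)} occupied band(s); "
            "need >= 3 for a regression"
        )
    x = [float(mids[i]) for i in occupied]
    y = [float(np.mean([sp.range_size_m for sp in members[i]])) for i in occupied]
    counts = [len(members[i]) for i in occupied]
    fit = fit_linear(x, y)
    result = MethodResult(
        method=method,
        x=x,
        y=y,
        species_counts=counts,
        fit=fit,
        supports_rapoport=_verdict(fit, alpha),
        band_indices=occupied,
        excluded_bands=excluded,
    )
    if with_quadratic and len(x) >= 4:
        qfit = fit_quadratic(x, y)
        result.quadratic_fit = qfit
        a = qfit.coefficients[0]
        result.unimodal = bool(a < 0 and min(x) < qfit.vertex_x < max(x))
    return result


def _verdict(fit: RegressionResult, alpha: float) -> str:
    if fit.p_value < alpha:
        return "positive" if fit.slope > 0 else "negative"
    return "inconclusive"


# ---------------------------------------------------------------------------
# The four methods


def stevens_method(
    ranges: Sequence[SpeciesRange],
    bands: ElevationBandSpec | None = None,
    alpha: float = 0.05,
) -> MethodResult:
    """Mean range of all species overlapping each band, regressed on band
    mid-elevation."""
    bands = bands or ElevationBandSpec()
    return _banded_result(
        "stevens", _band_members_overlap(ranges, bands), bands, alpha
    )


def pagel_method(
    ranges: Sequence[SpeciesRange],
    bands: ElevationBandSpec | None = None,
    alpha: float = 0.05,
) -> MethodResult:
    """Mean range of species whose upper range limit falls in each band."""
    bands = bands or ElevationBandSpec()
    return _banded_result(
        "pagel", _band_members_point(ranges, bands, "max_elev_m"), bands, alpha
    )


def rohde_midpoint_method(
    ranges: Sequence[SpeciesRange],
    bands: ElevationBandSpec | None = None,
    alpha: float = 0.05,
) -> MethodResult:
    """Mean range of species binned by range midpoint, with linear and
    parabolic fits and a unimodality flag."""
    bands = bands or ElevationBandSpec()
    return _banded_result(
        "rohde_midpoint",
        _band_members_point(ranges, bands, "midpoint_m"),
        bands,
        alpha,
        with_quadratic=True,
    )


def cross_species_method(
    ranges: Sequence[SpeciesRange], alpha: float = 0.05
) -> MethodResult:
    """Per-species scatter of range size against range midpoint, linear fit."""
    if len(ranges) < 3:
        raise ValueError(f"cross-species method needs >= 3 species, got {len(ranges)}")
    x = [sp.midpoint_m for sp in ranges]
    y = [sp.range_size_m for sp in ranges]
    fit = fit_linear(x, y)
    return MethodResult(
        method="cross_species",
        x=[float(v) for v in x],
        y=[float(v) for v in y],
        species_counts=[1] * len(ranges),
        fit=fit,
        supports_rapoport=_verdict(fit, alpha),
    )


def run_all_methods(
    ranges: Sequence[SpeciesRange],
    bands: ElevationBandSpec | None = None,
    alpha: float = 0.05,
    methods: Sequence[str] = METHODS,
) -> dict[str, MethodResult]:
    """Run the requested Rapoport tests and return results keyed by method."""
    bands = bands or ElevationBandSpec()
    dispatch = {
        "stevens": lambda: stevens_method(ranges, bands, alpha),
        "pagel": lambda: pagel_method(ranges, bands, alpha),
        "rohde_midpoint": lambda: rohde_midpoint_method(ranges, bands, alpha),
        "cross_species": lambda: cross_species_method(ranges, alpha),
    }
    unknown = set(methods) - set(dispatch)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}; choose from {METHODS}")
    return {m: dispatch[m]() for m in methods}
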