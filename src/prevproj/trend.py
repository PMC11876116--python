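"""Log-linear natural-spline trend model for grouped incidence estimates.

Published incidence estimates typically come as sex-specific rates for broad
age groups per calendar year.  To obtain a smooth incidence surface that can
be extrapolated past the observation window, the log incidence is regressed
on natural cubic splines of age (group midpoints) and calendar year, sex, and
all interactions up to the three-way age x year x sex product, by ordinary
least squares.  Natural splines are linear beyond their boundary knots, so
extrapolation in calendar year continues the boundary trend linearly on the
log scale.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .surfaces import SEXES

#: default representative age for the open-ended top age group
OPEN_GROUP_AGE = 85.0

_GROUP_RE = re.compile(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*$")
_OPEN_RE = re.compile(r"^\s*(?:>=|≥)?\s*(\d+)\s*\+?\s*$")


def midpoint_of(age_group: str, open_group_age: float = OPEN_GROUP_AGE) -> float:
    """Representative age for an age-group label.

    Closed groups like ``"18-34"`` map to their arithmetic midpoint; an
    open-ended group (``"80+"`` or ``">=80"``) maps to ``open_group_age``.
    """
    m = _GROUP_RE.match(str(age_group))
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        if hi <= lo:
            raise ValueError(f"degenerate age group {age_group!r}")
        return (lo + hi) / 2.0
    if _OPEN_RE.match(str(age_group)):
        return float(open_group_age)
    raise ValueError(f"unparseable age group label {age_group!r}")


def parse_age_group(age_group: str, top_age: float = 100.0) -> tuple[float, float]:
    """(lo, hi) integer-age span of a group label; open groups end at ``top_age``."""
    m = _GROUP_RE.match(str(age_group))
    if m:
        return float(m.group(1)), float(m.group(2))
    m = _OPEN_RE.match(str(age_group))
    if m:
        return float(m.group(1)), float(top_age)
    raise ValueError(f"unparseable age group label {age_group!r}")


@dataclass
class SplineSpec:
    """Knot layout of the age and year natural-spline bases.

    ``age_*`` describes a 4-knot natural cubic spline (2 boundary + 2
    interior), ``year_*`` a 3-knot one (1 interior).  Boundary knots default
    to the range of the observed midpoints / years, interior knots to
    quantiles (age) and the median year.
    """

    age_interior_knots: list[float]
    age_boundary: tuple[float, float]
    year_interior_knots: list[float]
    year_boundary: tuple[float, float]

    def __post_init__(self) -> None:
        self.age_interior_knots = [float(k) for k in self.age_interior_knots]
        self.year_interior_knots = [float(k) for k in self.year_interior_knots]
        self.age_boundary = (float(self.age_boundary[0]), float(self.age_boundary[1]))
        self.year_boundary = (float(self.year_boundary[0]), float(self.year_boundary[1]))
        lo, hi = self.age_boundary
        if not all(lo < k < hi for k in self.age_interior_knots):
            raise ValueError("age interior knots must lie strictly inside the boundary")
        lo, hi = self.year_boundary
        if not all(lo < k < hi for k in self.year_interior_knots):
            raise ValueError("year interior knots must lie strictly inside the boundary")

    @classmethod
    def from_data(cls, midpoints, years) -> "SplineSpec":
        mids = np.unique(np.asarray(midpoints, float))
        yrs = np.unique(np.asarray(years, float))
        if mids.size < 4:
            raise ValueError("need at least 4 distinct age midpoints")
        if yrs.size < 2:
            raise ValueError("need at least 2 distinct years")
        age_int = list(np.quantile(mids, [1 / 3, 2 / 3]))
        year_int = [float(np.median(yrs))]
        if not yrs[0] < year_int[0] < yrs[-1]:
            # two observed years: put the interior knot midway
            year_int = [float((yrs[0] + yrs[-1]) / 2.0)]
        return cls(age_int, (float(mids[0]), float(mids[-1])), year_int, (float(yrs[0]), float(yrs[-1])))

    def _age_formula(self) -> str:
        ak = [round(float(k), 6) for k in self.age_interior_knots]
        lo, hi = self.age_boundary
        return f"cr(age, knots={ak}, lower_bound={lo}, upper_bound={hi}) - 1"

    def _year_formula(self) -> str:
        yk = [round(float(k), 6) for k in self.year_interior_knots]
        lo, hi = self.year_boundary
        return f"cr(year, knots={yk}, lower_bound={lo}, upper_bound={hi}) - 1"

    def design_matrix(self, sex, age, year) -> tuple[np.ndarray, list[str], tuple]:
        """Full tensor-product design: spline(age) x spline(year) x sex.

        The age basis (4 natural-spline functions, spanning the constant) is
        crossed with the year basis (3 functions) and a {1, male} sex
        indicator, giving every main effect and interaction up to the
        three-way age x year x sex product in a single full-rank block.
        """
        sex_b, age_b, year_b = np.broadcast_arrays(
            np.asarray(sex), np.asarray(age, float), np.asarray(year, float)
        )
        shape = sex_b.shape
        A = np.asarray(patsy.dmatrix(self._age_formula(), {"age": age_b.ravel()}))
        Y = np.asarray(patsy.dmatrix(self._year_formula(), {"year": year_b.ravel()}))
        bad = set(np.unique(sex_b)) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex labels {sorted(bad)}")
        S = np.column_stack([np.ones(A.shape[0]), (sex_b.ravel() == "male").astype(float)])
        X = np.einsum("ni,nj,nk->nijk", A, Y, S).reshape(A.shape[0], -1)
        names = [
            f"age[{i}]:year[{j}]:{lvl}"
            for i in range(A.shape[1])
            for j in range(Y.shape[1])
            for lvl in ("1", "male")
        ]
        return X, names, shape


@dataclass
class IncidenceTrendModel:
    """Fitted log-incidence trend: spline spec and OLS coefficients."""

    spec: SplineSpec
    params: pd.Series
    diagnostics: dict = field(default_factory=dict)

    def predict_log(self, sex, age, year):
        X, names, shape = self.spec.design_matrix(sex, age, year)
        if list(self.params.index) != names:
            raise ValueError("coefficients do not match the design implied by the spec")
        out = (X @ self.params.to_numpy()).reshape(shape)
        return float(out) if out.ndim == 0 else out

    def predict(self, sex, age, year):
        """Incidence rate per person-year, exp(linear predictor); always > 0."""
        return np.exp(self.predict_log(sex, age, year))

    # -- plain-text persistence -------------------------------------------------

    def to_text(self) -> str:
        buf = io.StringIO()
        s = self.spec
        buf.write("# incidence trend model (log-rate natural-spline OLS)\n")
        buf.write(f"age_interior_knots: {','.join(repr(k) for k in s.age_interior_knots)}\n")
        buf.write(f"age_boundary: {s.age_boundary[0]!r},{s.age_boundary[1]!r}\n")
        buf.write(f"year_interior_knots: {','.join(repr(k) for k in s.year_interior_knots)}\n")
        buf.write(f"year_boundary: {s.year_boundary[0]!r},{s.year_boundary[1]!r}\n")
        buf.write("coefficients:\n")
        for name, value in self.params.items():
            buf.write(f"  {name} = {value!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "IncidenceTrendModel":
        fields: dict[str, str] = {}
        coefs: dict[str, float] = {}
        in_coefs = False
        for line in text.splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line.startswith("coefficients:"):
                in_coefs = True
                continue
            if in_coefs:
                name, value = line.rsplit("=", 1)
                coefs[name.strip()] = float(value)
            else:
                key, value = line.split(":", 1)
                fields[key.strip()] = value.strip()

        def floats(key):
            return [float(v) for v in fields[key].split(",")]

        spec = SplineSpec(
            floats("age_interior_knots"),
            tuple(floats("age_boundary")),
            floats("year_interior_knots"),
            tuple(floats("year_boundary")),
        )
        _, names, _ = spec.design_matrix(
            np.array(SEXES * 2), np.full(4, spec.age_boundary[0]), np.full(4, spec.year_boundary[0])
        )
        params = pd.Series(coefs)
        if list(params.index) != names:
            raise ValueError("stored coefficients do not match the design implied by the spec")
        return cls(spec=spec, params=params)


def fit_incidence_trend(
    estimates: pd.DataFrame,
    spec: SplineSpec | None = None,
    open_group_age: float = OPEN_GROUP_AGE,
) -> IncidenceTrendModel:
    """OLS fit of log incidence on spline(age) x spline(year) x sex.

    ``estimates`` needs columns ``sex``, ``year``, ``rate`` and either
    ``age`` (numeric) or ``age_group`` (labels, converted via
    :func:`midpoint_of`).  All rates must be strictly positive.  Raises if the
    design is rank deficient or has more parameters than observations.
    """
    df = estimates.copy()
    if "age" not in df.columns:
        if "age_group" not in df.columns:
            raise ValueError("estimates need an 'age' or 'age_group' column")
        df["age"] = [midpoint_of(g, open_group_age) for g in df["age_group"]]
    for col in ("sex", "year", "rate"):
        if col not in df.columns:
            raise ValueError(f"estimates are missing the '{col}' column")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels {sorted(bad_sex)}")
    if set(df["sex"]) != set(SEXES):
        raise ValueError("estimates must contain both sexes")
    if np.any(df["rate"].to_numpy(float) <= 0):
        raise ValueError("all incidence rates must be > 0 for the log transform")
    if df["year"].nunique() < 2:
        raise ValueError("need estimates from at least 2 distinct years")
    if df["age"].nunique() < 4:
        raise ValueError("need at least 4 distinct age midpoints")

    if spec is None:
        spec = SplineSpec.from_data(df["age"], df["year"])
    y = np.log(df["rate"].to_numpy(float))
    Xa, names, _ = spec.design_matrix(df["sex"].to_numpy(), df["age"].to_numpy(float), df["year"].to_numpy(float))
    if Xa.shape[0] < Xa.shape[1]:
        raise ValueError(
            f"only {Xa.shape[0]} observations for {Xa.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("design matrix is rank deficient; add years/ages or simplify the spline spec")
    fit = sm.OLS(y, Xa).fit()
    params = pd.Series(fit.params, index=names)
    resid = y - Xa @ fit.params
    diagnostics = {
        "nobs": int(Xa.shape[0]),
        "nparams": int(Xa.shape[1]),
        "resid_max_abs": float(np.max(np.abs(resid))),
        "resid_rms": float(np.sqrt(np.mean(resid**2))),
        "rsquared": float(fit.rsquared),
    }
    return IncidenceTrendModel(spec=spec, params=params, diagnostics=diagnostics)


def predict_incidence(model: IncidenceTrendModel, sex, age, year):
    """Functional alias for :meth:`IncidenceTrendModel.predict`."""
    return model.predict(sex, age, year)
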