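"""Salt-titration analysis: normalisation, sigmoidal fit, c1/2 comparison.

Nucleosome disassembly is forced by increasing NaCl concentration and read
out as a drop in the (normalised) ensemble proximity ratio P.  The salt
series is described by a four-parameter logistic

    P(x) = P(0) + (P(inf) - P(0)) / (1 + exp((c_half - x) / b))

where x is NaCl in mM, P(0) and P(inf) the low- and high-salt plateaus,
c_half the inflection point (the stability readout) and b the width at the
inflection.  The fit is exposed statsmodels-style: ``SaltTitrationModel``
is built from a replicate-level table or from aggregated points and
``fit()`` returns a ``SaltTitrationResults`` with estimates, standard
errors, covariance and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model as LmModel

from ._errors import FitError, ValidationError

__all__ = [
    "TitrationPoint",
    "SaltTitrationModel",
    "SaltTitrationResults",
    "TitrationFit",
    "logistic4",
    "normalize_series",
    "fit_titration",
    "compare_constructs",
]

PLATEAU_MAX_MM = 100.0  # low-salt points (<= this) define the normalisation
SD_FLOOR = 1e-3         # replicate-SD floor for 1/sd^2 weights


def logistic4(x, p0: float, p_inf: float, c_half: float, b: float):
    """Four-parameter logistic, decreasing for b > 0 and p_inf < p0."""
    x = np.asarray(x, dtype=float)
    return p0 + (p_inf - p0) / (1.0 + np.exp((c_half - x) / b))


@dataclass(frozen=True)
class TitrationPoint:
    """One salt condition: NaCl (mM), replicate mean/SD of P, replicate n."""

    nacl_mm: float
    p_mean: float
    p_sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self):
        if self.nacl_mm < 0:
            raise ValidationError("nacl_mm must be >= 0")
        if self.p_sd < 0:
            raise ValidationError("p_sd must be >= 0")


def normalize_series(points: list[TitrationPoint]) -> list[TitrationPoint]:
    """Divide p_mean and p_sd by the mean P of the low-salt plateau.

    The plateau is the mean over points with NaCl <= 100 mM, so the
    normalised curve starts at ~1.  Idempotent on already-normalised data.
    """
    plateau = [p.p_mean for p in points if p.nacl_mm <= PLATEAU_MAX_MM]
    if not plateau:
        raise ValidationError("no point at <= 100 mM NaCl to normalise to")
    ref = float(np.mean(plateau))
    if ref <= 0:
        raise ValidationError(f"low-salt plateau mean is {ref} <= 0")
    return [TitrationPoint(p.nacl_mm, p.p_mean / ref, p.p_sd / ref,
                           p.n_replicates) for p in points]


class SaltTitrationModel:
    """Sigmoidal disassembly model for one construct's salt series.

    Parameters
    ----------
    points
        Aggregated titration points (one per concentration).
    weighting
        ``None`` (default) fits unweighted; ``"1/sd2"`` weights residuals
        by 1/p_sd^2 when all SDs are positive.  With few replicates the
        SD estimates are noisy and weighting by them degrades both the
        c1/2 recovery and the SE calibration, hence the default.
    """

    def __init__(self, points: list[TitrationPoint],
                 weighting: str | None = None):
        concs = sorted({p.nacl_mm for p in points})
        if len(concs) < 5:
            raise ValidationError(
                f"need >= 5 distinct concentrations, got {len(concs)}")
        self.points = sorted(points, key=lambda p: p.nacl_mm)
        self.weighting = weighting

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalize: bool = True,
                       **kwargs) -> "SaltTitrationModel":
        """Build from a replicate-level table with columns nacl_mm, p.

        Replicates are aggregated per concentration into mean and SD; the
        series is normalised to the low-salt plateau unless ``normalize``
        is False.
        """
        g = df.groupby("nacl_mm")["p"]
        points = [TitrationPoint(float(c), float(m), float(s), int(n))
                  for c, m, s, n in zip(g.mean().index, g.mean(),
                                        g.std(ddof=1).fillna(0.0), g.count())]
        if normalize:
            points = normalize_series(points)
        return cls(points, **kwargs)

    def fit(self) -> "SaltTitrationResults":
        x = np.array([p.nacl_mm for p in self.points])
        y = np.array([p.p_mean for p in self.points])
        sds = np.array([p.p_sd for p in self.points])
        if np.ptp(y) < 1e-12:
            raise ValidationError("no transition: series is flat")
        weights = None
        if self.weighting == "1/sd2" and np.all(sds > 0):
            weights = 1.0 / np.maximum(sds, SD_FLOOR) ** 2

        model = LmModel(logistic4)
        span = float(x.max() - x.min())
        params = model.make_params(
            p0=float(y[np.argmin(x)]),
            p_inf=float(y[np.argmax(x)]),
            c_half=float(0.5 * (x.min() + x.max())),
            b=span / 20.0,
        )
        params["c_half"].set(min=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = model.fit(y, params, x=x, weights=weights)

        p0 = float(out.params["p0"].value)
        p_inf = float(out.params["p_inf"].value)
        c_half = float(out.params["c_half"].value)
        b = float(out.params["b"].value)
        # resolve the sign convention: an increasing fit of a decreasing
        # curve flips (p0, p_inf) and negates b; c_half stays the midpoint
        if (y[0] - y[-1]) * (p0 - p_inf) < 0:
            p0, p_inf, b = p_inf, p0, -b
        se = out.params["c_half"].stderr
        cov = out.covar
        return SaltTitrationResults(
            model=self, p0=p0, p_inf=p_inf, c_half_mm=c_half, slope_b=b,
            se_c_half=float(se) if se is not None else np.nan,
            covariance=cov,
            converged=bool(out.success),
            extrapolated=not (x.min() <= c_half <= x.max()),
            residual_sse=float(np.sum(out.residual ** 2)),
        )


@dataclass
class SaltTitrationResults:
    """Fitted logistic parameters, uncertainties and diagnostics."""

    model: SaltTitrationModel | None
    p0: float
    p_inf: float
    c_half_mm: float
    slope_b: float
    se_c_half: float
    covariance: np.ndarray | None = None
    converged: bool = True
    extrapolated: bool = False
    residual_sse: float = np.nan
    label: str = ""

    def predict(self, x) -> np.ndarray:
        return logistic4(x, self.p0, self.p_inf, self.c_half_mm, self.slope_b)

    def summary(self) -> str:
        lines = [f"Salt-titration sigmoidal fit {self.label}".rstrip(),
                 "=" * 44,
                 f"P(0)      {self.p0:>10.4f}",
                 f"P(inf)    {self.p_inf:>10.4f}",
                 f"c1/2 (mM) {self.c_half_mm:>10.2f} +/- {self.se_c_half:.2f}",
                 f"b (mM)    {self.slope_b:>10.2f}",
                 f"SSE       {self.residual_sse:>10.3e}",
                 f"converged {self.converged}"]
        if self.extrapolated:
            lines.append("warning: c1/2 outside the fitted concentration span")
        return "\n".join(lines)


# -- functional surface -----------------------------------------------------

TitrationFit = SaltTitrationResults


def fit_titration(points: list[TitrationPoint],
                  weighting: str | None = None) -> SaltTitrationResults:
    """Fit the four-parameter logistic to a titration series."""
    return SaltTitrationModel(points, weighting=weighting).fit()


def compare_constructs(fits: dict[str, SaltTitrationResults]) -> pd.DataFrame:
    """Pairwise comparison of c1/2 values across constructs.

    Returns one row per construct pair with the difference, the pooled-SE
    z-score and a verdict: ``coinciding`` when |z| < 2 (the signature of
    the RE mutants, whose dimer-interface opening and dimer eviction occur
    at the same ionic strength), else ``distinct``.  Pairs lacking a
    standard error are skipped with a warning.
    """
    if len(fits) < 2:
        raise ValidationError("need >= 2 fits to compare")
    rows = []
    for (la, fa), (lb, fb) in itertools.combinations(fits.items(), 2):
        if not (np.isfinite(fa.se_c_half) and np.isfinite(fb.se_c_half)):
            warnings.warn(f"missing SE for pair ({la}, {lb}); skipped")
            continue
        pooled = np.hypot(fa.se_c_half, fb.se_c_half)
        z = (fa.c_half_mm - fb.c_half_mm) / pooled if pooled > 0 else np.inf
        rows.append({
            "construct_a": la, "construct_b": lb,
            "c_half_a_mm": fa.c_half_mm, "c_half_b_mm": fb.c_half_mm,
            "se_a_mm": fa.se_c_half, "se_b_mm": fb.se_c_half,
            "delta_mm": fa.c_half_mm - fb.c_half_mm,
            "z": z,
            "verdict": "coinciding" if abs(z) < 2 else "distinct",
        })
    return pd.DataFrame(rows)
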