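"""Site-frequency-spectrum neutrality tests with coalescent-simulated nulls.

Implements Tajima's D, the outgroup-free Fu & Li D* and F* (with the
corrected variance coefficients that the standard desktop popgen software
uses; the 1993 originals carry known typos), and the Ramos-Onsins & Rozas
R2 statistic. Significance for all four comes from one machinery: neutral
constant-size coalescent genealogies conditioned on the observed sample
size n with exactly S mutations placed uniformly on total branch length,
and the empirical tail probability with the (count+1)/(reps+1) correction.

Negative D/D*/F* and small R2 indicate an excess of rare variants —
demographic expansion or selection; the lower tail is therefore the
default alternative for every statistic here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coalsim import CoalescentParams, _rng, drop_mutations, simulate_genealogy
from .haplotypes import DiversitySummary

STATISTICS = ("D", "Dstar", "Fstar", "R2")


@dataclass
class NeutralityResult:
    statistic: str
    value: float
    p_value: float | None = None
    n_reps: int = 0
    seed: int | None = None
    intermediates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "value": self.value,
            "p_value": self.p_value,
            "n_reps": self.n_reps,
            "seed": self.seed,
            **{k: v for k, v in self.intermediates.items() if np.isscalar(v)},
        }


# ---------------------------------------------------------------------------
# Coefficients (functions of n only)


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def tajima_coefficients(n: int) -> dict:
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def fu_li_star_coefficients(n: int) -> dict:
    # a_n, b_n as in the source formulas; a_{n+1} = a_n + 1/n
    an = harmonic(n)
    bn = harmonic(n, 2)
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    )
    vD = (
        (n / (n - 1.0)) ** 2 * bn
        + an**2 * dn
        - 2.0 * (n * an * (an + 1.0)) / (n - 1.0) ** 2
    ) / (an**2 + bn)
    uD = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vD
    vF = (
        dn
        + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
        - (2.0 / (n - 1.0)) * (4.0 * bn - 6.0 + 8.0 / n)
    ) / (an**2 + bn)
    uF = (
        n / (n - 1.0)
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + 2.0 * (n + 1.0) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1.0))
    ) / an - vF
    return dict(an=an, bn=bn, cn=cn, dn=dn, uD=uD, vD=vD, uF=uF, vF=vF)


# ---------------------------------------------------------------------------
# Statistics from sufficient statistics


def _check(ds: DiversitySummary, min_n: int) -> None:
    if ds.n < min_n:
        raise ValueError(f"statistic requires n >= {min_n}, got n={ds.n}")
    if ds.S < 1:
        raise ValueError("statistic undefined, no variation (S = 0)")


def _tajima_value(n, S, k, coef) -> float:
    var = coef["e1"] * S + coef["e2"] * S * (S - 1)
    return (k - S / coef["a1"]) / math.sqrt(var)


def _dstar_value(n, S, eta_s, coef) -> float:
    var = coef["uD"] * S + coef["vD"] * S * S
    return ((n / (n - 1.0)) * S - coef["an"] * eta_s) / math.sqrt(var)


def _fstar_value(n, S, eta_s, k, coef) -> float:
    var = coef["uF"] * S + coef["vF"] * S * S
    return (k - ((n - 1.0) / n) * eta_s) / math.sqrt(var)


def _r2_value(n, S, k, U) -> float:
    return float(math.sqrt(np.mean((np.asarray(U) - k / 2.0) ** 2)) / S)


def tajima_d(ds: DiversitySummary) -> NeutralityResult:
    """Tajima's D: standardized contrast of k against S/a1."""
    _check(ds, 4)
    coef = tajima_coefficients(ds.n)
    value = _tajima_value(ds.n, ds.S, ds.k, coef)
    return NeutralityResult("D", value, intermediates={**coef, "n": ds.n, "S": ds.S, "k": ds.k})


def fu_li_dstar(ds: DiversitySummary) -> NeutralityResult:
    """Fu & Li's D* (no outgroup): contrasts S with total singletons."""
    _check(ds, 4)
    coef = fu_li_star_coefficients(ds.n)
    value = _dstar_value(ds.n, ds.S, ds.eta_s, coef)
    return NeutralityResult(
        "Dstar", value,
        intermediates={**coef, "n": ds.n, "S": ds.S, "eta_s": ds.eta_s},
    )


def fu_li_fstar(ds: DiversitySummary) -> NeutralityResult:
    """Fu & Li's F* (no outgroup): contrasts k with total singletons."""
    _check(ds, 4)
    coef = fu_li_star_coefficients(ds.n)
    value = _fstar_value(ds.n, ds.S, ds.eta_s, ds.k, coef)
    return NeutralityResult(
        "Fstar", value,
        intermediates={**coef, "n": ds.n, "S": ds.S, "eta_s": ds.eta_s, "k": ds.k},
    )


def r2_statistic(ds: DiversitySummary) -> NeutralityResult:
    """Ramos-Onsins & Rozas R2 = sqrt(mean (U_i - k/2)^2) / S."""
    _check(ds, 2)
    value = _r2_value(ds.n, ds.S, ds.k, ds.U)
    return NeutralityResult(
        "R2", value, intermediates={"n": ds.n, "S": ds.S, "k": ds.k, "eta_s": ds.eta_s}
    )


COMPUTE = {
    "D": tajima_d,
    "Dstar": fu_li_dstar,
    "Fstar": fu_li_fstar,
    "R2": r2_statistic,
}


# ---------------------------------------------------------------------------
# Coalescent null machinery


def _suff_from_matrix(mat: np.ndarray) -> tuple:
    """(S, eta_s, U, k) from a binary derived-state matrix (sites x tips).

    Binary columns under the no-outgroup singleton rule: derived count 1
    attributes the singleton to the derived carrier, derived count n-1 to
    the sole ancestral carrier.
    """
    n = mat.shape[1]
    x = mat.sum(axis=1)
    S = mat.shape[0]
    k = float((2.0 * x * (n - x)).sum() / (n * (n - 1)))
    U = np.zeros(n)
    for col in np.nonzero(x == 1)[0]:
        U[int(np.nonzero(mat[col])[0][0])] += 1
    if n > 2:
        for col in np.nonzero(x == n - 1)[0]:
            U[int(np.nonzero(~mat[col])[0][0])] += 1
    return S, int(U.sum()), U, k


def simulate_statistics(
    n: int,
    S: int,
    reps: int,
    seed: int,
    growth: float = 0.0,
    statistics=STATISTICS,
) -> dict:
    """Arrays of each requested statistic under the (possibly growing)
    fixed-S coalescent; the null distribution engine."""
    if S < 1:
        raise ValueError("fixed-S simulation needs S >= 1")
    rng = _rng(seed)
    tcoef = tajima_coefficients(n) if "D" in statistics else None
    fcoef = (
        fu_li_star_coefficients(n)
        if ("Dstar" in statistics or "Fstar" in statistics)
        else None
    )
    p = CoalescentParams(n=n, mode="fixed_S", S=S, growth=growth)
    out = {s: np.empty(reps) for s in statistics}
    for r in range(reps):
        gen = simulate_genealogy(p, rng=rng)
        mat = drop_mutations(gen, "fixed_S", S, rng=rng)
        Ssim, eta_s, U, k = _suff_from_matrix(mat)
        if "D" in out:
            out["D"][r] = _tajima_value(n, Ssim, k, tcoef)
        if "Dstar" in out:
            out["Dstar"][r] = _dstar_value(n, Ssim, eta_s, fcoef)
        if "Fstar" in out:
            out["Fstar"][r] = _fstar_value(n, Ssim, eta_s, k, fcoef)
        if "R2" in out:
            out["R2"][r] = _r2_value(n, Ssim, k, U)
    return out


def coalescent_pvalue(
    result: NeutralityResult,
    n: int,
    S: int,
    reps: int = 10000,
    seed: int = 0,
    tail: str = "lower",
    null: np.ndarray | None = None,
) -> NeutralityResult:
    """Attach an empirical coalescent p-value to a computed statistic.

    ``null`` may carry a precomputed null sample (same n, S) to share one
    simulation across several observed values.
    """
    if result.statistic not in STATISTICS:
        raise ValueError(f"no coalescent null for statistic {result.statistic!r}")
    if null is None:
        if reps < 1000:
            raise ValueError("use at least 1000 replicates for empirical p-values")
        null = simulate_statistics(n, S, reps, seed, statistics=(result.statistic,))[
            result.statistic
        ]
    reps = len(null)
    lower = (int((null <= result.value).sum()) + 1) / (reps + 1)
    upper = (int((null >= result.value).sum()) + 1) / (reps + 1)
    if tail == "lower":
        p = lower
    elif tail == "upper":
        p = upper
    elif tail == "two-sided":
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return NeutralityResult(
        result.statistic, result.value, p_value=p, n_reps=reps, seed=seed,
        intermediates=dict(result.intermediates),
    )


def neutrality_suite(
    ds: DiversitySummary, reps: int = 10000, seed: int = 0
) -> list[NeutralityResult]:
    """All four tests with p-values from one shared null simulation."""
    nulls = simulate_statistics(ds.n, ds.S, reps, seed)
    out = []
    for name in STATISTICS:
        res = COMPUTE[name](ds)
        out.append(
            coalescent_pvalue(res, ds.n, ds.S, seed=seed, null=nulls[name])
        )
    return out
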