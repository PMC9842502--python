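"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: the bootstrap
oracle loops in pure Python over the same seed stream, and the measure-
combination oracle works from raw budget fluxes (never the activity ×
emission-factor decomposition) and evaluates every prefix of the
priority order exhaustively.
"""

import math

import numpy as np
from scipy.stats import norm, t as t_dist


def oracle_bootstrap(lnr, n_boot, seed, level=0.95, method="bc"):
    """Loop-based resampling on the same seed stream as bootstrap_effect.

    Returns (point, ci_low, ci_high) on the percent-change scale.
    """
    lnr = sorted(map(float, lnr))  # order-invariance convention
    n = len(lnr)
    theta = sum(lnr) / n
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.array([sum(lnr[i] for i in row) / n for row in idx])
    # Expanded (t-calibrated) tail level shared by both interval variants.
    za = math.sqrt(n / (n - 1.0)) * t_dist.ppf((1.0 - level) / 2.0, df=n - 1)
    if method == "percentile":
        alpha = norm.cdf(za)
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    else:
        below = sum(1 for b in boot if b < theta)
        ties = sum(1 for b in boot if b == theta)
        p0 = (below + 0.5 * ties) / n_boot
        p0 = min(max(p0, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
        z0 = norm.ppf(p0)
        lo = np.quantile(boot, norm.cdf(2 * z0 + za))
        hi = np.quantile(boot, norm.cdf(2 * z0 - za))

    def pct(x):
        return (math.exp(x) - 1.0) * 100.0

    return pct(theta), pct(float(lo)), pct(float(hi))


_PATHWAY_FLUX = {
    "NH3": "e_nh3",
    "NOx": "e_nox",
    "N2O": "e_n2o",
    "leaching": "n_leach",
    "runoff": "n_runoff",
}


def oracle_combine(budget, measures, target, interactions=None):
    """Exhaustive prefix evaluation of the measure-combination rules.

    Works directly from budget fluxes (ΔE = flux × η × X, which equals
    A × EF × η × X for any baseline-consistent decomposition) and scans
    every prefix of the priority order for the first that reaches the
    NUE target.  Returns (selected ids, delta_e dict, nue_post).
    """
    region = budget.region
    interactions = {tuple(sorted(k)): dict(v)
                    for k, v in (interactions or {}).items()}
    n_input = (budget.n_fer + budget.n_man + budget.n_fix + budget.n_dep
               + budget.n_irr)
    nr_base = sum(getattr(budget, a) for a in _PATHWAY_FLUX.values())

    def standalone(m):
        return sum(
            getattr(budget, a) * m.eta.get(j, 0.0)
            * m.implementation_rate.get(region, 0.0)
            for j, a in _PATHWAY_FLUX.items()
        )

    order = sorted(
        measures, key=lambda m: (m.tier, -standalone(m), m.measure_id)
    )

    def evaluate(sel):
        ids = {m.measure_id: m for m in sel}
        delta = {}
        for j, attr in _PATHWAY_FLUX.items():
            flux = getattr(budget, attr)
            remaining = {
                mid: m.implementation_rate.get(region, 0.0)
                for mid, m in ids.items()
            }
            eta_x = 0.0
            for (a, b) in sorted(interactions):
                if a in ids and b in ids:
                    xp = min(remaining[a], remaining[b])
                    eta_x += interactions[(a, b)].get(j, 0.0) * xp
                    remaining[a] -= xp
                    remaining[b] -= xp
            for mid, m in ids.items():
                eta_x += m.eta.get(j, 0.0) * remaining[mid]
            delta[j] = min(flux * eta_x, flux)
        d_total = sum(delta.values())
        d_n2 = budget.e_n2 * min(d_total / nr_base, 1.0) if nr_base > 0 else 0.0
        ymult = 1.0
        for m in sel:
            ymult *= 1.0 + (m.yield_multiplier - 1.0) * m.implementation_rate.get(
                region, 0.0
            )
        harvest_post = min(
            budget.n_harvest * ymult, max(target.target_harvest, budget.n_harvest)
        )
        d_input = d_total + d_n2 - (harvest_post - budget.n_harvest)
        input_post = max(n_input - d_input, harvest_post)
        nue_post = harvest_post / input_post if input_post > 0 else 1.0
        return delta, nue_post

    for k in range(len(order) + 1):
        prefix = order[:k]
        delta, nue_post = evaluate(prefix)
        if nue_post >= target.nue_target:
            return [m.measure_id for m in prefix], delta, nue_post
    delta, nue_post = evaluate(order)
    return [m.measure_id for m in order], delta, nue_post
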