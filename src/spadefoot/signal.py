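"""Pagel's-lambda phylogenetic signal estimation.

Lambda multiplies the off-diagonal entries of the Brownian tip covariance:
0 means relatives are no more similar than random species (star phylogeny),
1 means similarity tracks shared branch lengths exactly.  The estimate is
the ML fit of the lambda model; likelihood-ratio tests against the two
boundary hypotheses (lambda = 0, lambda = 1) use chi-square(1) with the
50:50 boundary mixture convention (the p-value is halved because the
alternative is one-sided at a parameter boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .evomodels import _align, _check_input, _profile_fit, fit_lambda
from .tree import TimeTree, lambda_scale, phylo_covariance

__all__ = ["SignalResult", "pagels_lambda", "signal_battery"]


@dataclass
class SignalResult:
    trait_name: str
    lambda_hat: float
    loglik_at_hat: float
    loglik_at_0: float
    loglik_at_1: float
    p_vs_0: float
    p_vs_1: float
    n: int
    #: p-value convention for the boundary LR tests
    test_convention: str = "chi2(1) 50:50 boundary mixture (halved p)"


def _boundary_lr_p(ll_hat: float, ll_0: float) -> float:
    """Halved chi-square(1) p-value for an LR test at a parameter boundary."""
    lr = max(0.0, 2.0 * (ll_hat - ll_0))
    if lr == 0.0:
        return 1.0
    return min(1.0, 0.5 * float(stats.chi2.sf(lr, df=1)))


def pagels_lambda(y, tree: TimeTree, trait_name: str = "trait") -> SignalResult:
    """Estimate phylogenetic signal in one trait.

    Raises for a constant trait (lambda is unidentifiable).
    """
    yv, labels = _align(y, tree)
    if _check_input(yv):
        raise ValueError(f"trait {trait_name!r} is constant; signal undefined")
    fit = fit_lambda(pd.Series(yv, index=labels), tree)
    cov = phylo_covariance(tree).subset(labels)
    ll0 = _profile_fit(yv, lambda_scale(cov, 0.0).V)[2]
    ll1 = _profile_fit(yv, lambda_scale(cov, 1.0).V)[2]
    return SignalResult(
        trait_name=trait_name,
        lambda_hat=fit.shape,
        loglik_at_hat=fit.loglik,
        loglik_at_0=ll0,
        loglik_at_1=ll1,
        p_vs_0=_boundary_lr_p(fit.loglik, ll0),
        p_vs_1=_boundary_lr_p(fit.loglik, ll1),
        n=fit.n,
    )


def signal_battery(traits: pd.DataFrame, tree: TimeTree, variables) -> pd.DataFrame:
    """Signal estimates for each named trait column, in the given order.

    Near-zero estimates are kept as-is (reported in scientific notation at
    the presentation layer, never floored).
    """
    if traits.index.name != "species" and "species" in traits.columns:
        traits = traits.set_index("species")
    rows = []
    for name in variables:
        if name not in traits.columns:
            raise KeyError(
                f"unknown variable {name!r}; available columns: "
                f"{sorted(traits.columns)}"
            )
        r = pagels_lambda(traits[name], tree, trait_name=name)
        rows.append(
            {
                "variable": name,
                "n": r.n,
                "lambda": r.lambda_hat,
                "loglik": r.loglik_at_hat,
                "p_vs_0": r.p_vs_0,
                "p_vs_1": r.p_vs_1,
            }
        )
    return pd.DataFrame(rows)
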