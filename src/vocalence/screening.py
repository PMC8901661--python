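"""Parameter screening: PCA-based selection and mixed-model effect sizes.

The ten acoustic parameters are strongly inter-correlated within their
categories (e.g. the three spectral quartiles).  A principal component
analysis on the standardized parameters, run per call type, picks one
non-redundant representative per category: components with eigenvalue > 1
are retained and, within each category, the parameter with the largest
absolute loading on any retained component wins (ties broken
alphabetically, for reproducibility).

Each selected parameter is then modelled with a Gaussian linear mixed
model: ``outcome ~ factor + age_class`` with a random intercept for the
recording team and for pig nested in team.  The factor of interest
(valence or context) is tested with a maximum-likelihood likelihood-ratio
test, and its effect size is summarized by the marginal R2 — the share of
total variance (fixed + random + residual) explained by the fixed effects
alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import CATEGORY_MAP, PARAMETERS

__all__ = ["PcaSelection", "LmmResult", "select_parameters", "fit_valence_lmm", "marginal_r2"]


@dataclass
class PcaSelection:
    call_type: str
    loadings: pd.DataFrame  # parameter x component
    eigenvalues: np.ndarray
    retained_components: int
    selected: list  # 4 parameter names, one per category


@dataclass
class LmmResult:
    outcome: str
    factor: str
    coefficients: dict  # fixed-effect name -> estimate
    var_team: float
    var_pig: float
    var_resid: float
    var_fixed: float  # variance of the fixed-effect linear predictor
    p_value: float
    converged: bool = True
    notes: list = field(default_factory=list)

    @property
    def marginal_r2(self) -> float:
        return marginal_r2(self)


def select_parameters(features: pd.DataFrame, call_type: str) -> PcaSelection:
    """Pick one parameter per category by PCA loading magnitude.

    Rows of the requested call type with any missing parameter are dropped
    (listwise); the PCA runs on z-scored columns, i.e. on the correlation
    matrix.  Loadings are eigenvectors scaled by sqrt(eigenvalue) so each
    entry is the correlation between parameter and component.
    """
    sub = features.loc[features["call_type"] == call_type, PARAMETERS].dropna()
    if len(sub) < 10:
        raise ValueError(f"need >= 10 complete rows of call type {call_type}")
    sd = sub.std(ddof=1)
    if (sd == 0).any():
        degenerate = list(sd.index[sd == 0])
        warnings.warn(f"constant parameters excluded from PCA: {degenerate}")
    cols = list(sd.index[sd > 0])
    z = (sub[cols] - sub[cols].mean()) / sub[cols].std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = int(np.sum(eigval > 1.0)) or 1
    load = eigvec[:, :retained] * np.sqrt(np.maximum(eigval[:retained], 0.0))
    loadings = pd.DataFrame(load, index=cols,
                            columns=[f"PC{i+1}" for i in range(retained)])
    selected = []
    for category in ["Duration", "Amplitude modulation", "Spectrum", "Tonality/noise"]:
        members = sorted(p for p in cols if CATEGORY_MAP[p] == category)
        if not members:
            raise ValueError(f"category {category!r} has no measurable parameter")
        best = max(members, key=lambda p: (loadings.loc[p].abs().max(), [-ord(c) for c in p]))
        selected.append(best)
    return PcaSelection(call_type=call_type, loadings=loadings, eigenvalues=eigval,
                        retained_components=retained, selected=selected)


def _fixed_design(data: pd.DataFrame, factor: str) -> pd.DataFrame:
    import patsy

    return patsy.dmatrix(f"C({factor}) + C(age_class)", data, return_type="dataframe")


def fit_valence_lmm(features: pd.DataFrame, outcome: str, factor: str = "valence") -> LmmResult:
    """Fit ``outcome ~ factor + age_class + (1 | team / pig)`` by ML.

    The p-value is a likelihood-ratio test of the factor against the model
    without it.  Degenerate designs are handled contractually: a constant
    outcome returns zero variance components and p = 1 with a warning; a
    single team yields a zero team component.
    """
    import statsmodels.formula.api as smf

    data = features.dropna(subset=[outcome]).copy()
    if data[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    y = data[outcome].to_numpy(float)
    notes = []
    if np.var(y) < 1e-14 * max(1.0, np.mean(y) ** 2):
        warnings.warn(f"{outcome} is constant; degenerate LMM result returned")
        return LmmResult(outcome=outcome, factor=factor, coefficients={},
                         var_team=0.0, var_pig=0.0, var_resid=0.0, var_fixed=0.0,
                         p_value=1.0, converged=True, notes=["constant outcome"])

    single_team = data["team_id"].nunique() < 2
    if single_team:
        warnings.warn("single team: team variance component fixed at 0")
        groups, vcf = data["pig_id"], None
    else:
        groups, vcf = data["team_id"], {"pig": "0 + C(pig_id)"}

    formula = f"{outcome} ~ C({factor}) + C(age_class)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm(formula, data, groups=groups, re_formula="1",
                           vc_formula=vcf).fit(reml=False)
        red = smf.mixedlm(f"{outcome} ~ C(age_class)", data, groups=groups,
                          re_formula="1", vc_formula=vcf).fit(reml=False)

    lr = max(0.0, 2.0 * (full.llf - red.llf))
    df = data[factor].nunique() - 1
    p = float(sps.chi2.sf(lr, df)) if lr > 0 else 1.0

    if single_team:
        var_team, var_pig = 0.0, float(full.cov_re.iloc[0, 0])
    else:
        var_team = float(full.cov_re.iloc[0, 0])
        var_pig = float(full.vcomp[0]) if full.vcomp.size else 0.0
    X = _fixed_design(data, factor)
    beta = full.fe_params.reindex(X.columns).to_numpy()
    var_fixed = float(np.var(X.to_numpy() @ beta, ddof=1))
    return LmmResult(
        outcome=outcome, factor=factor,
        coefficients=dict(full.fe_params),
        var_team=var_team, var_pig=var_pig,
        var_resid=float(full.scale), var_fixed=var_fixed,
        p_value=p, converged=bool(full.converged), notes=notes,
    )


def marginal_r2(result: LmmResult) -> float:
    """Marginal R2: var(fixed predictor) / (fixed + team + pig + residual).

    0 when the fixed effects explain nothing, 1 when they explain
    everything; raises if every variance term is zero.
    """
    total = result.var_fixed + result.var_team + result.var_pig + result.var_resid
    if total <= 0:
        if result.notes and "constant outcome" in result.notes:
            return 0.0
        raise ValueError("all variance components are zero")
    return float(result.var_fixed / total)
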