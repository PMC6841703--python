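"""Driver-screening statistics for the priming effect.

Zero-order and controlled partial correlations (with the percent change
in coefficient that measures how much a controlled variable carries the
association), variation partitioning of adjusted R^2 across the four
covariate groups, and per-group PC1 extraction.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    """(Partial) correlation between two variables, t-test significance."""

    x_var: str
    y_var: str
    controls: tuple[str, ...]
    r: float
    p: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 2 - len(self.controls)


@dataclass
class PartitionFractions:
    """Adjusted-R^2 decomposition across named predictor groups.

    ``raw`` maps each non-empty subset of groups (frozenset) to its
    exclusive explained fraction; negatives are kept raw there and
    truncated to zero in ``truncated`` (flagged), following the
    convention that a group explaining less than random normal
    variables explains nothing.
    """

    groups: tuple[str, ...]
    raw: dict[frozenset, float]
    truncated: dict[frozenset, float]
    truncated_flags: dict[frozenset, bool]
    full_adj_r2: float
    residual: float

    def unique(self, group: str, raw: bool = False) -> float:
        src = self.raw if raw else self.truncated
        return src[frozenset([group])]


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Residuals of v after least-squares on controls plus intercept."""
    x = np.column_stack([np.ones(len(v)), controls])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_correlation(
    y: np.ndarray,
    x: np.ndarray,
    controls: np.ndarray | None = None,
    x_var: str = "x",
    y_var: str = "y",
    control_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Correlation of y and x after removing the controls' linear effect.

    Both variables are regressed on the control matrix (with intercept);
    the Pearson correlation of the residuals is tested against a t
    distribution with n - 2 - q degrees of freedom (q controls).  With
    no controls this reduces exactly to the ordinary Pearson r.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if controls is None or (hasattr(controls, "size") and controls.size == 0):
        controls = np.empty((len(y), 0))
    controls = np.asarray(controls, dtype=float)
    if controls.ndim == 1:
        controls = controls[:, None]
    if not len(y) == len(x) == len(controls):
        raise ValueError("y, x and controls must have equal length")
    q = controls.shape[1]
    n = len(y)
    if n <= q + 2:
        raise ValueError(f"need n > {q + 2} observations for {q} controls")
    ry = _residualize(y, controls)
    rx = _residualize(x, controls)
    sy, sx = np.linalg.norm(ry), np.linalg.norm(rx)
    if sy < 1e-12 * max(1.0, float(np.linalg.norm(y))) or \
       sx < 1e-12 * max(1.0, float(np.linalg.norm(x))):
        raise ValueError(
            "controls perfectly predict x or y; partial correlation undefined"
        )
    r = float(np.dot(rx, ry) / (sx * sy))
    r = min(max(r, -1.0), 1.0)
    dof = n - 2 - q
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return CorrelationResult(
        x_var=x_var, y_var=y_var, controls=tuple(control_names),
        r=r, p=p, n=n,
    )


def coefficient_change(
    zero_order: dict[str, CorrelationResult] | pd.DataFrame,
    controlled: list[CorrelationResult] | pd.DataFrame,
) -> pd.DataFrame:
    """Percent loss of correlation strength under control.

    100 (|r_zero| - |r_controlled|) / |r_zero| per (variable, control)
    pair; negative values mean the association strengthened.  Pairs with
    r_zero == 0 are flagged undefined (NaN).
    """
    if isinstance(zero_order, pd.DataFrame):
        zmap = {
            (r.x_var, r.y_var): r.r for r in zero_order.itertuples()
        }
    else:
        zmap = {(c.x_var, c.y_var): c.r for c in zero_order.values()}
    rows = []
    iterable = (
        controlled.itertuples() if isinstance(controlled, pd.DataFrame)
        else controlled
    )
    for c in iterable:
        key = (c.x_var, c.y_var)
        if key not in zmap:
            raise KeyError(f"no zero-order correlation for pair {key}")
        r0 = zmap[key]
        ctrl = c.controls[0] if len(c.controls) == 1 else ",".join(c.controls)
        change = (
            np.nan if r0 == 0
            else 100.0 * (abs(r0) - abs(c.r)) / abs(r0)
        )
        rows.append({
            "x_var": c.x_var, "y_var": c.y_var, "control": ctrl,
            "r_zero": r0, "r_controlled": c.r, "pct_change": change,
        })
    return pd.DataFrame(rows)


def _adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Ezekiel-adjusted R^2 of an OLS fit with intercept."""
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("too few observations for predictor count")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient model: collinear predictor columns")
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partitioning(
    y: np.ndarray,
    groups: dict[str, np.ndarray],
) -> PartitionFractions:
    """Unique and shared adjusted-R^2 fractions across predictor groups.

    Fits all 2^g - 1 subset models, converts each to Ezekiel-adjusted
    R^2, and solves the inclusion-exclusion system for the exclusive
    fraction of every subset (the fraction explained jointly by exactly
    those groups).  Raw fractions sum to the full-model adjusted R^2;
    negatives are truncated to zero (flagged) in the headline table.
    """
    y = np.asarray(y, dtype=float)
    names = tuple(groups)
    mats = {}
    for name in names:
        m = np.asarray(groups[name], dtype=float)
        if m.ndim == 1:
            m = m[:, None]
        if m.shape[1] == 0:
            raise ValueError(f"group {name!r} has no predictor columns")
        mats[name] = m

    subsets = [
        frozenset(c)
        for size in range(1, len(names) + 1)
        for c in itertools.combinations(names, size)
    ]
    adj = {
        s: _adjusted_r2(y, np.column_stack([mats[g] for g in names if g in s]))
        for s in subsets
    }
    # A(T) = sum of exclusive fractions x(S) over S intersecting T
    m = np.array(
        [[1.0 if s & t else 0.0 for s in subsets] for t in subsets]
    )
    x = np.linalg.solve(m, np.array([adj[t] for t in subsets]))
    raw = dict(zip(subsets, (float(v) for v in x)))
    truncated = {s: max(v, 0.0) for s, v in raw.items()}
    flags = {s: v < 0.0 for s, v in raw.items()}
    full = adj[frozenset(names)]
    return PartitionFractions(
        groups=names, raw=raw, truncated=truncated, truncated_flags=flags,
        full_adj_r2=full, residual=1.0 - full,
    )


def partition_to_frame(pf: PartitionFractions) -> pd.DataFrame:
    """Flatten a PartitionFractions into the varpart.csv layout."""
    rows = []
    for s in sorted(pf.raw, key=lambda s: (len(s), sorted(s))):
        rows.append({
            "fraction": "+".join(sorted(s)),
            "raw": pf.raw[s],
            "truncated": pf.truncated[s],
            "was_truncated": pf.truncated_flags[s],
        })
    rows.append({
        "fraction": "residual", "raw": pf.residual,
        "truncated": pf.residual, "was_truncated": False,
    })
    return pd.DataFrame(rows)


def group_pc1(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of a site x variable matrix.

    Columns are standardized (zero mean, unit SD) so PC1 is the leading
    eigenvector of the correlation matrix; scores are oriented to
    correlate positively with the first column.  Returns (scores,
    variance explained in %).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 sites")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        cols = (
            [matrix.columns[i] for i in bad]
            if isinstance(matrix, pd.DataFrame) else bad.tolist()
        )
        raise ValueError(f"constant column(s): {cols}")
    z = (x - x.mean(axis=0)) / sd
    corr = z.T @ z / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    scores = z @ lead
    if np.corrcoef(scores, z[:, 0])[0, 1] < 0:
        scores = -scores
    variance_pct = 100.0 * evals[-1] / evals.sum()
    return scores, float(variance_pct)


# ---------------------------------------------------------------------------
# table-level drivers screen

def drivers_screen(
    covariates_wide: pd.DataFrame,
    response: pd.Series,
    control_group: str = "som_stability",
) -> dict[str, pd.DataFrame]:
    """Run the full screening battery on a wide covariate table.

    For every variable outside ``control_group``: the zero-order
    correlation with the response and the partial correlation
    controlling each ``control_group`` variable one at a time, plus the
    percent coefficient change; variation partitioning across the four
    groups; PC1 per group.  Sites missing the response are dropped;
    remaining missing values use listwise deletion per correlation.
    """
    common = covariates_wide.index.intersection(response.dropna().index)
    wide = covariates_wide.loc[common]
    y = response.loc[common].to_numpy(dtype=float)

    groups_present = [g for g in wide.columns.get_level_values(0).unique()]
    controls = (
        wide[control_group].columns.tolist()
        if control_group in groups_present else []
    )

    zero_rows, ctl_rows = [], []
    for group in groups_present:
        for var in wide[group].columns:
            xv = wide[(group, var)].to_numpy(dtype=float)
            mask = ~np.isnan(xv) & ~np.isnan(y)
            res = partial_correlation(
                y[mask], xv[mask], None, x_var=var, y_var="priming"
            )
            zero_rows.append({
                "x_var": var, "y_var": "priming", "group": group,
                "control": "", "r": res.r, "p": res.p, "n": res.n,
            })
            if group == control_group:
                continue
            for ctl in controls:
                cv = wide[(control_group, ctl)].to_numpy(dtype=float)
                m = mask & ~np.isnan(cv)
                res_c = partial_correlation(
                    y[m], xv[m], cv[m], x_var=var, y_var="priming",
                    control_names=(ctl,),
                )
                ctl_rows.append({
                    "x_var": var, "y_var": "priming", "group": group,
                    "control": ctl, "r": res_c.r, "p": res_c.p, "n": res_c.n,
                })
    zero_df = pd.DataFrame(zero_rows)
    ctl_df = pd.DataFrame(ctl_rows)

    ctl_results = [
        CorrelationResult(
            x_var=r.x_var, y_var=r.y_var, controls=(r.control,),
            r=r.r, p=r.p, n=r.n,
        )
        for r in ctl_df.itertuples()
    ]
    change = coefficient_change(zero_df, ctl_results) if ctl_results else pd.DataFrame()

    complete = ~wide.isna().any(axis=1) & ~pd.isna(response.loc[wide.index])
    wc = wide.loc[complete]
    yc = response.loc[wc.index].to_numpy(dtype=float)
    varpart = variation_partitioning(
        yc, {g: wc[g].to_numpy(dtype=float) for g in groups_present}
    )

    pc1_rows = []
    for group in groups_present:
        scores, var_pct = group_pc1(wc[group])
        for site, score in zip(wc.index, scores):
            pc1_rows.append({
                "site_id": site, "group": group, "score": score,
                "variance_explained": var_pct,
            })
    return {
        "zero_order": zero_df,
        "controlled": ctl_df,
        "coefficient_change": change,
        "varpart": partition_to_frame(varpart),
        "pc1": pd.DataFrame(pc1_rows),
    }
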