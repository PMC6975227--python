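"""Two-branch differential expression for zero-inflated tumor/normal RNA-seq.

Molecules are first pre-filtered on their zero fraction among NORMAL samples
(default: eliminated if >10% zeros), then routed by their zero fraction among
TUMOR samples: molecules with <30% tumor zeros enter a continuous branch
(Welch t-test + fold-change cutoffs), the rest an ON/OFF binary branch
(two-sided Fisher's exact test on the detected/not-detected x tumor/normal
contingency). Both branches are Benjamini-Hochberg adjusted, by default
separately within each branch and RNA class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

_PSEUDO = 1e-9  # guards a fold-change denominator that is exactly zero

STATUSES = ("up", "down", "on_in_cancer", "off_in_cancer", "not_de")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def prefilter_by_normal_zeros(
    expr: ExpressionMatrix, max_zero_frac: float = 0.10
) -> ExpressionMatrix:
    """Drop molecules whose zero fraction among normal samples exceeds the cut.

    Molecules detected in essentially all normal tissue are kept; anything with
    more than ``max_zero_frac`` zeros among normals is eliminated. Row order of
    the survivors is preserved.
    """
    if len(expr.normal_samples) == 0:
        raise ValueError("prefilter requires at least one normal sample")
    zf = expr.zero_fraction("normal")
    return expr.subset_molecules(expr.molecules[zf.values <= max_zero_frac])


def route_by_tumor_zeros(
    expr: ExpressionMatrix, zero_frac_cut: float = 0.30
) -> tuple[pd.Index, pd.Index]:
    """Partition molecules into (continuous-branch, binary-branch) ids.

    A molecule is tested continuously iff its zero fraction among tumor samples
    is strictly below ``zero_frac_cut``; exactly at the cut it goes binary.
    """
    if len(expr.tumor_samples) == 0:
        raise ValueError("routing requires at least one tumor sample")
    zf = expr.zero_fraction("tumor")
    cont = expr.molecules[zf.values < zero_frac_cut]
    binary = expr.molecules[zf.values >= zero_frac_cut]
    return cont, binary


def test_continuous(
    expr: ExpressionMatrix,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Welch t-test + fold-change calls for the continuous branch.

    fold_change = mean(tumor) / mean(normal) on raw values (a tiny pseudo-count
    enters the denominator only if it is exactly zero). Status is ``up`` when
    fold_change > fc_up and BH-adjusted p < alpha, ``down`` when
    fold_change < fc_down and adjusted p < alpha, else ``not_de``.
    BH is applied across the molecules passed in (callers group by RNA class).
    """
    t_cols, n_cols = expr.tumor_samples, expr.normal_samples
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("continuous testing needs >= 2 samples per condition")
    tv = expr.values[t_cols].to_numpy(float)
    nv = expr.values[n_cols].to_numpy(float)
    mean_t, mean_n = tv.mean(axis=1), nv.mean(axis=1)
    fc = mean_t / np.where(mean_n == 0, _PSEUDO, mean_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(tv, nv, axis=1, equal_var=False).pvalue
    zero_var = (tv.var(axis=1) == 0) & (nv.var(axis=1) == 0)
    p = np.where(zero_var & (mean_t == mean_n), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)  # degenerate molecules are never called
    fdr = benjamini_hochberg(p)
    status = np.full(len(p), "not_de", dtype=object)
    status[(fc > fc_up) & (fdr < alpha)] = "up"
    status[(fc < fc_down) & (fdr < alpha)] = "down"
    return pd.DataFrame(
        {
            "molecule_id": expr.molecules,
            "class": expr.molecule_class.values,
            "branch": "continuous",
            "fold_change": fc,
            "on_freq_tumor": np.nan,
            "on_freq_normal": np.nan,
            "p_value": p,
            "fdr": fdr,
            "status": status,
        }
    )


def test_binary(
    expr: ExpressionMatrix, on_ratio: float = 2.0, fdr_cut: float = 0.01
) -> pd.DataFrame:
    """ON/OFF Fisher's exact calls for the binary branch.

    A molecule is ON in a sample when its value is > 0. Direction is
    ``on_in_cancer`` when on_freq_tumor >= on_ratio * on_freq_normal (ties at
    exactly the ratio count as ON-in-cancer), else ``off_in_cancer``; the
    direction becomes the status only when the BH-adjusted two-sided Fisher
    p-value drops below ``fdr_cut``.
    """
    t_cols, n_cols = expr.tumor_samples, expr.normal_samples
    if len(t_cols) == 0 or len(n_cols) == 0:
        raise ValueError("binary testing needs both conditions present")
    on_t = (expr.values[t_cols] > 0).sum(axis=1).to_numpy()
    on_n = (expr.values[n_cols] > 0).sum(axis=1).to_numpy()
    nt, nn = len(t_cols), len(n_cols)
    freq_t, freq_n = on_t / nt, on_n / nn
    p = np.array(
        [
            stats.fisher_exact(
                [[a, b], [nt - a, nn - b]], alternative="two-sided"
            ).pvalue
            for a, b in zip(on_t, on_n)
        ]
    )
    fdr = benjamini_hochberg(p)
    direction = np.where(freq_t >= on_ratio * freq_n, "on_in_cancer", "off_in_cancer")
    status = np.where(fdr < fdr_cut, direction, "not_de")
    return pd.DataFrame(
        {
            "molecule_id": expr.molecules,
            "class": expr.molecule_class.values,
            "branch": "binary",
            "fold_change": np.nan,
            "on_freq_tumor": freq_t,
            "on_freq_normal": freq_n,
            "p_value": p,
            "fdr": fdr,
            "status": status,
        }
    )


def call_differential_expression(
    expr: ExpressionMatrix,
    prefilter: float = 0.10,
    zero_route: float = 0.30,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.01,
    on_ratio: float = 2.0,
    per_class: bool = True,
) -> pd.DataFrame:
    """Full DE workflow: prefilter, route, test both branches, concatenate.

    With ``per_class=True`` (default) BH adjustment is applied separately for
    each (branch, RNA class) stratum; ``per_class=False`` pools classes within
    a branch.
    """
    kept = prefilter_by_normal_zeros(expr, prefilter)
    cont_ids, bin_ids = route_by_tumor_zeros(kept, zero_route)
    frames = []
    for branch_ids, tester, kwargs in (
        (cont_ids, test_continuous, dict(fc_up=fc_up, fc_down=fc_down, alpha=alpha)),
        (bin_ids, test_binary, dict(on_ratio=on_ratio, fdr_cut=alpha)),
    ):
        if len(branch_ids) == 0:
            continue
        sub = kept.subset_molecules(branch_ids)
        if per_class:
            for cls in pd.unique(sub.molecule_class):
                part = sub.of_class(cls)
                if len(part.molecules):
                    frames.append(tester(part, **kwargs))
        else:
            frames.append(tester(sub, **kwargs))
    if not frames:
        return pd.DataFrame(
            columns=["molecule_id", "class", "branch", "fold_change",
                     "on_freq_tumor", "on_freq_normal", "p_value", "fdr", "status"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.set_index("molecule_id").loc[
        [m for m in kept.molecules if m in out["molecule_id"].values]
    ].reset_index()
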