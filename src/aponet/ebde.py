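"""Empirical-Bayes negative-binomial two-group differential expression.

Model
-----
Counts of transcript *g* in sample *i* are negative binomial with size
``r_gi = r_g * s_i`` (``s_i`` a median-of-ratios size factor) and success
probability ``q_g`` drawn from a shared Beta(alpha, beta) prior.  Integrating
``q_g`` out gives the beta-negative-binomial marginal over a sample set S:

    f(x_S) = prod_i C(x_i + r_i - 1, x_i)
             * B(alpha + sum_i r_i, beta + sum_i x_i) / B(alpha, beta)

Equal expression (EE) shares one q across both groups; differential
expression (DE) draws an independent q per group, so f_DE = f(S_A) * f(S_B).
A two-point mixture with weight ``p_de`` on DE is fitted by EM: the E-step
computes the posterior probability of DE (PPDE) per transcript, the M-step
sets ``p_de`` to the mean PPDE and re-optimises (alpha, beta) on the
posterior-weighted log marginal.  PPEE = 1 - PPDE.

The per-transcript sizes ``r_g`` come from method-of-moments dispersion
estimated on size-factor-scaled counts within each condition (so a real
between-group shift is not mistaken for overdispersion), moderated toward
the ensemble median dispersion with prior weight equal to the residual
degrees of freedom, inverted and capped to [1e-2, 1e3]; ``v <= m`` caps
high (near-Poisson).  The sizes are held fixed during EM.

The two-step workflow mirrors the study design: step 1 tests every genotype
pair within each multi-genotype phenotypic class and keeps transcripts that
are equally expressed (PPEE >= 0.95) in all pairs; step 2 runs the pairwise
class comparisons on the transcripts expressed and retained in every class,
calling a transcript overexpressed when PPDE >= 0.95 and |log2FC| >= 1.5.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp

from .expression import ExpressionMatrix, validate_metadata

_R_MIN, _R_MAX = 1e-2, 1e3


@dataclass
class EBConfig:
    ppde_threshold: float = 0.95
    log2fc_threshold: float = 1.5
    pseudocount: float = 1.0
    max_iter: int = 50
    tol_p: float = 1e-4
    tol_loglik: float = 1e-6
    init_alpha: float = 1.0
    init_beta: float = 1.0
    init_p_de: float = 0.05
    size_factors: pd.Series | None = None


@dataclass
class EBModel:
    alpha: float
    beta: float
    p_de: float
    size_factors: pd.Series
    r: pd.Series
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)
    excluded_all_zero: list = field(default_factory=list)


def estimate_size_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization.

    For transcripts with no zero count, s_i = median_g of
    C(g,i) / geometric-mean_g; transcripts containing any zero are excluded
    from the median.
    """
    data = counts.data if isinstance(counts, ExpressionMatrix) else counts
    arr = data.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no transcript has nonzero counts in every sample; size factors "
            "are undefined — consider adding pseudo-counts")
    ref = arr[all_nonzero]
    geomean = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    s = np.median(ref / geomean, axis=0)
    return pd.Series(s, index=data.columns)


def beta_nb_predictive(x, r, alpha: float, beta: float) -> float:
    """Log beta-negative-binomial marginal of counts ``x`` with sizes ``r``.

    Computed entirely in log space; raises on a non-finite result rather
    than propagating NaN.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if x.shape != r.shape:
        raise ValueError("x and r must have matching shapes")
    if alpha <= 0 or beta <= 0 or (r <= 0).any() or (x < 0).any():
        raise ValueError("alpha, beta, r must be > 0 and x >= 0")
    log_comb = (gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)).sum()
    out = log_comb + betaln(alpha + r.sum(), beta + x.sum()) - betaln(alpha, beta)
    if not np.isfinite(out):
        raise FloatingPointError(
            f"non-finite beta-NB log density (alpha={alpha}, beta={beta})")
    return float(out)


def _log_comb_rows(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    return (gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)).sum(axis=1)


def _marginal_rows(log_comb, r_sum, x_sum, alpha, beta):
    return log_comb + betaln(alpha + r_sum, beta + x_sum) - betaln(alpha, beta)


def moment_size_parameters(scaled: np.ndarray, groups=None) -> np.ndarray:
    """Per-transcript NB size by method of moments on scaled counts.

    When ``groups`` (lists of column indices) are given, the dispersion
    phi = (v - m) / m^2 is estimated within each group and combined by a
    degrees-of-freedom-weighted average, which keeps a genuine mean shift
    between the groups from being absorbed as overdispersion.  Gene-wise
    dispersions are then moderated toward the ensemble median (prior weight
    = residual df) before inverting to r.  Pooling across all samples is
    the fallback when no grouping is supplied.
    """
    if groups is None:
        groups = [list(range(scaled.shape[1]))]

    # work on the dispersion scale phi = 1/r, where var = m + phi * m^2
    num = np.zeros(scaled.shape[0])
    den = np.zeros(scaled.shape[0])
    residual_df = 0.0
    for cols in groups:
        if len(cols) < 2:
            continue
        sub = scaled[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, np.clip((v - m) / (m * m), 0.0, None), np.nan)
        w = float(len(cols) - 1)
        residual_df += w
        ok = np.isfinite(phi)
        num[ok] += w * phi[ok]
        den[ok] += w
    if residual_df == 0:  # all groups single-sample: pooled fallback
        m = scaled.mean(axis=1)
        v = scaled.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, np.clip((v - m) / (m * m), 0.0, None), np.nan)
        num, den = np.nan_to_num(phi), np.isfinite(phi).astype(float)
        residual_df = 1.0

    with np.errstate(invalid="ignore"):
        phi_hat = np.where(den > 0, num / np.clip(den, 1e-12, None), np.nan)
    finite = phi_hat[np.isfinite(phi_hat)]
    phi_prior = float(np.median(finite)) if finite.size else 0.0
    # moderate gene-wise dispersion toward the ensemble median with prior
    # weight equal to the residual df: a handful of replicates cannot pin
    # down a gene's dispersion, and unmoderated underestimates inflate the
    # false-discovery rate
    prior_df = residual_df
    phi = np.where(np.isfinite(phi_hat),
                   (den * phi_hat + prior_df * phi_prior) / (den + prior_df),
                   phi_prior)
    r = 1.0 / np.clip(phi, 1.0 / _R_MAX, None)
    return np.clip(r, _R_MIN, _R_MAX)


def ppde_from_marginals(log_f_ee, log_f_de, p_de: float) -> np.ndarray:
    """Posterior DE probability from the two log marginals and mixture weight."""
    p_de = min(max(p_de, 1e-12), 1 - 1e-12)
    log_de = np.log(p_de) + np.asarray(log_f_de)
    log_ee = np.log1p(-p_de) + np.asarray(log_f_ee)
    return np.exp(log_de - np.logaddexp(log_de, log_ee))


def fit_two_group(
    counts: ExpressionMatrix,
    group_a,
    group_b,
    config: EBConfig | None = None,
) -> tuple[EBModel, pd.DataFrame]:
    """Fit the EE/DE mixture for two sample groups and score every transcript.

    Returns the fitted model and a posterior table indexed by transcript with
    columns PPEE, PPDE, log2FC (group A over group B, pseudocount-stabilised
    normalized means), is_de (PPDE at or above the threshold) and call in
    {over_in_A, over_in_B, not_DE} labelling the overexpression direction for
    DEGs whose |log2FC| clears the fold-change threshold.  Transcripts
    that are all-zero across both groups have no defined posterior and are
    excluded from the table (ids recorded on the model and in
    ``table.attrs["excluded_all_zero"]``).
    """
    config = config or EBConfig()
    # canonical sample order inside each group: permuting replicates then
    # leaves every posterior bit-identical, not merely equal in expectation
    group_a, group_b = sorted(group_a), sorted(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        warnings.warn("fewer than 2 samples in a group; posteriors will be weak")
    samples = group_a + group_b
    data = counts.data.loc[:, samples]

    all_zero = (data.to_numpy() == 0).all(axis=1)
    excluded = list(data.index[all_zero])
    if excluded:
        warnings.warn(f"{len(excluded)} all-zero transcripts excluded from the EB fit")
    data = data.loc[~all_zero]

    if config.size_factors is not None:
        s = config.size_factors.loc[samples]
    else:
        s = estimate_size_factors(ExpressionMatrix(data, unit="count"))
    s_arr = s.to_numpy(dtype=float)

    x = data.to_numpy(dtype=float)
    scaled = x / s_arr[None, :]
    idx_a = [samples.index(c) for c in group_a]
    idx_b = [samples.index(c) for c in group_b]
    r_g = moment_size_parameters(scaled, groups=[idx_a, idx_b])
    r = r_g[:, None] * s_arr[None, :]
    xa, xb = x[:, idx_a], x[:, idx_b]
    ra, rb = r[:, idx_a], r[:, idx_b]

    # log-binomial-coefficient terms are (alpha, beta)-free: precompute once
    lc_all = _log_comb_rows(x, r)
    lc_a = _log_comb_rows(xa, ra)
    lc_b = _log_comb_rows(xb, rb)
    rs_all, xs_all = r.sum(axis=1), x.sum(axis=1)
    rs_a, xs_a = ra.sum(axis=1), xa.sum(axis=1)
    rs_b, xs_b = rb.sum(axis=1), xb.sum(axis=1)

    def marginals(alpha, beta):
        f_ee = _marginal_rows(lc_all, rs_all, xs_all, alpha, beta)
        f_de = (_marginal_rows(lc_a, rs_a, xs_a, alpha, beta)
                + _marginal_rows(lc_b, rs_b, xs_b, alpha, beta))
        return f_ee, f_de

    def observed_loglik(f_ee, f_de, p_de):
        p_de = min(max(p_de, 1e-12), 1 - 1e-12)
        return float(logsumexp(
            np.column_stack([np.log1p(-p_de) + f_ee, np.log(p_de) + f_de]),
            axis=1).sum())

    alpha, beta, p_de = config.init_alpha, config.init_beta, config.init_p_de
    f_ee, f_de = marginals(alpha, beta)
    ll = observed_loglik(f_ee, f_de, p_de)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        prev_p = p_de
        ppde = ppde_from_marginals(f_ee, f_de, p_de)

        new_p = float(np.mean(ppde))

        def neg_q(params):
            a, b = np.exp(params)
            ee = _marginal_rows(lc_all, rs_all, xs_all, a, b)
            de = (_marginal_rows(lc_a, rs_a, xs_a, a, b)
                  + _marginal_rows(lc_b, rs_b, xs_b, a, b))
            return -float(np.sum((1.0 - ppde) * ee + ppde * de))

        res = minimize(neg_q, x0=np.log([alpha, beta]), method="L-BFGS-B",
                       bounds=[(np.log(1e-6), np.log(1e6))] * 2)
        alpha, beta = np.exp(res.x)
        p_de = new_p

        f_ee, f_de = marginals(alpha, beta)
        new_ll = observed_loglik(f_ee, f_de, p_de)
        if new_ll < trace[-1] - 1e-8 * (1.0 + abs(trace[-1])):
            raise RuntimeError("EM decreased the observed-data log likelihood")
        rel_dll = abs(new_ll - trace[-1]) / (1.0 + abs(trace[-1]))
        dp = abs(p_de - prev_p)
        trace.append(new_ll)
        if dp < config.tol_p and rel_dll < config.tol_loglik:
            converged = True
            break
    if not converged:
        warnings.warn("EM did not converge; returning last iterate")

    ppde = ppde_from_marginals(f_ee, f_de, p_de)
    ppee = 1.0 - ppde

    c = config.pseudocount
    m_a, m_b = scaled[:, idx_a].mean(axis=1), scaled[:, idx_b].mean(axis=1)
    log2fc = np.log2((m_a + c) / (m_b + c))

    # DE status is posterior-based; the fold-change threshold only assigns
    # the overexpression direction, so a DEG with |log2FC| below it keeps
    # is_de=True but call=not_DE (no direction label)
    is_de = ppde >= config.ppde_threshold
    call = np.where(is_de & (log2fc >= config.log2fc_threshold), "over_in_A",
                    np.where(is_de & (log2fc <= -config.log2fc_threshold),
                             "over_in_B", "not_DE"))

    table = pd.DataFrame(
        {"PPEE": ppee, "PPDE": ppde, "log2FC": log2fc, "is_de": is_de,
         "call": call},
        index=data.index)
    table.attrs["excluded_all_zero"] = excluded
    model = EBModel(alpha=float(alpha), beta=float(beta), p_de=float(p_de),
                    size_factors=s, r=pd.Series(r_g, index=data.index),
                    converged=converged, n_iter=n_iter, loglik_trace=trace,
                    excluded_all_zero=excluded)
    return model, table


def de_called(table: pd.DataFrame) -> set:
    """Transcripts called DE (posterior criterion; direction not required)."""
    if "is_de" in table.columns:
        return set(table.index[table["is_de"]])
    return set(table.index[table["call"] != "not_DE"])


def consistent_degs(table_1: pd.DataFrame, table_2: pd.DataFrame) -> set:
    """Transcripts DE-called in both comparisons (either direction)."""
    return de_called(table_1) & de_called(table_2)


@dataclass
class WorkflowConfig:
    ppee_threshold: float = 0.95
    epsilon: float = 0.0
    focus_class: str = "4X_apo"
    eb: EBConfig = field(default_factory=EBConfig)


@dataclass
class WorkflowResult:
    classes: list
    expressed_in_class: dict            # class -> set of transcript ids
    step1_retained: dict                # class -> set of transcript ids
    step1_tables: dict                  # (class, genoA, genoB) -> posterior table
    common_expressed: set
    comparisons: dict                   # (classA, classB) -> posterior table
    consistent_degs: set

    def summary(self) -> dict:
        return {
            "expressed_in_class": {k: len(v) for k, v in self.expressed_in_class.items()},
            "step1_retained": {k: len(v) for k, v in self.step1_retained.items()},
            "common_expressed": len(self.common_expressed),
            "de_called": {"|".join(pair): len(de_called(t))
                          for pair, t in self.comparisons.items()},
            "consistent_degs": len(self.consistent_degs),
        }


def _expressed_in_class(data: pd.DataFrame, class_meta: pd.DataFrame,
                        epsilon: float) -> set:
    flags = None
    arr = data.to_numpy()
    col = {sid: j for j, sid in enumerate(data.columns)}
    for _, geno_records in class_meta.groupby("genotype"):
        cols = [col[sid] for sid in geno_records["sample_id"]]
        detected = (arr[:, cols] > epsilon).any(axis=1)
        flags = detected if flags is None else flags & detected
    return set(data.index[flags])


def two_step_workflow(
    counts: ExpressionMatrix,
    meta: pd.DataFrame,
    config: WorkflowConfig | None = None,
) -> WorkflowResult:
    """Within-class equal-expression filter followed by between-class DE calls.

    Step 1: for every phenotypic class with at least two genotypes, every
    genotype pair is tested (clones as replicates) and only transcripts with
    PPEE >= threshold in all pairs are retained; a transcript whose counts
    are all zero in a pair carries no evidence against equal expression and
    is retained by that pair.  Single-genotype classes skip step 1 and retain
    all transcripts expressed in the class.  Step 2 compares every class pair
    on the intersection of retained-and-expressed transcripts.
    """
    config = config or WorkflowConfig()
    validate_metadata(meta, counts)
    meta = meta.loc[meta["sample_id"].isin(counts.sample_ids)]
    classes = list(dict.fromkeys(meta["phenotypic_class"]))
    if len(classes) < 2:
        raise ValueError("need at least 2 phenotypic classes")

    expressed: dict = {}
    retained: dict = {}
    step1_tables: dict = {}
    for cls in classes:
        class_meta = meta.loc[meta["phenotypic_class"] == cls]
        expressed[cls] = _expressed_in_class(counts.data, class_meta, config.epsilon)
        genotypes = list(dict.fromkeys(class_meta["genotype"]))
        if len(genotypes) < 2:
            retained[cls] = set(counts.transcript_ids)
            continue
        keep = set(counts.transcript_ids)
        for g1, g2 in itertools.combinations(genotypes, 2):
            cols_1 = class_meta.loc[class_meta["genotype"] == g1, "sample_id"].tolist()
            cols_2 = class_meta.loc[class_meta["genotype"] == g2, "sample_id"].tolist()
            _, table = fit_two_group(counts, cols_1, cols_2, config.eb)
            step1_tables[(cls, g1, g2)] = table
            failing = set(table.index[table["PPEE"] < config.ppee_threshold])
            keep -= failing
        retained[cls] = keep

    common = set(counts.transcript_ids)
    for cls in classes:
        common &= retained[cls] & expressed[cls]

    common_matrix = counts.subset_transcripts(sorted(common)) if common else None
    comparisons: dict = {}
    for cls_a, cls_b in itertools.combinations(classes, 2):
        if common_matrix is None:
            comparisons[(cls_a, cls_b)] = pd.DataFrame(
                columns=["PPEE", "PPDE", "log2FC", "call"])
            continue
        cols_a = meta.loc[meta["phenotypic_class"] == cls_a, "sample_id"].tolist()
        cols_b = meta.loc[meta["phenotypic_class"] == cls_b, "sample_id"].tolist()
        _, table = fit_two_group(common_matrix, cols_a, cols_b, config.eb)
        comparisons[(cls_a, cls_b)] = table

    focus = config.focus_class
    focus_tables = [t for pair, t in comparisons.items() if focus in pair]
    if not focus_tables:
        warnings.warn(f"focus class {focus!r} not among classes; "
                      "consistent-DEG set left empty")
        consistent: set = set()
    else:
        consistent = de_called(focus_tables[0])
        for t in focus_tables[1:]:
            consistent &= de_called(t)

    return WorkflowResult(
        classes=classes,
        expressed_in_class=expressed,
        step1_retained=retained,
        step1_tables=step1_tables,
        common_expressed=common,
        comparisons=comparisons,
        consistent_degs=consistent,
    )
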