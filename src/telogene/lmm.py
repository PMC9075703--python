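"""Linear mixed model for telomere-length association, statsmodels-style.

The model for the (batch-corrected) telomere length y of n related samples is

    y = X beta + g + e,      g ~ N(0, sg2 * K),
    e_i ~ N(0, sigma2_{group(i)})   independently,

with X the fixed-effect covariates (age, sex, study, ancestry PCs, ...),
K a sparse relatedness matrix (unit diagonal), sg2 the additive genetic
variance, and a separate residual variance per study/population group
(heteroskedasticity across strata).  Variance components are estimated by
average-information REML; because K is block diagonal over families the
solver factorizes the phenotype covariance family-block by family-block
(batched over equal-sized blocks), so fits scale linearly in n.

:class:`TelomereLMM` is the model; :meth:`TelomereLMM.fit` returns a
:class:`TelomereLMMResults` carrying the estimates, their uncertainties, the
marginal residuals and a covariance solver used by the downstream score
tests.  The genome-wide analysis uses the fully adjusted two-stage form
(:class:`TwoStageLMM`): fit the model, rank-inverse-normalize and rescale
its marginal residuals, refit the identical model on the transformed
outcome, then test variants against the Stage-2 fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.csgraph import connected_components

from .data import KinshipMatrix


class ConvergenceError(RuntimeError):
    """AI-REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# block-structured covariance


class BlockCovariance:
    """Sigma = sg2 * K + diag(residual variance by group).

    K's zero pattern is decomposed into connected components (families);
    blocks of equal size are stacked so Cholesky/solve/inverse run batched.
    A dense K degenerates gracefully to a single block.
    """

    def __init__(self, kinship: np.ndarray | sparse.spmatrix,
                 group_idx: np.ndarray, n_groups: int):
        k_sparse = sparse.csr_matrix(kinship)
        n = k_sparse.shape[0]
        n_comp, labels = connected_components(k_sparse != 0, directed=False)
        self.n = n
        self.group_idx = np.asarray(group_idx)
        self.n_groups = n_groups
        # group block indices by size for batched linear algebra
        self._by_size: list[tuple[np.ndarray, np.ndarray]] = []
        members_of = [np.flatnonzero(labels == c) for c in range(n_comp)]
        sizes = np.array([m.size for m in members_of])
        k_dense_blocks = {}
        for s in np.unique(sizes):
            idx = np.stack([members_of[c] for c in np.flatnonzero(sizes == s)])
            nb = idx.shape[0]
            kb = np.empty((nb, s, s))
            for b in range(nb):
                kb[b] = k_sparse[idx[b]][:, idx[b]].toarray()
            k_dense_blocks[s] = kb
            self._by_size.append((idx, kb))
        self._sinv: list[np.ndarray] = []
        self._logdet = np.nan

    def set_params(self, sg2: float, res_vars: np.ndarray) -> None:
        self._sinv = []
        logdet = 0.0
        for idx, kb in self._by_size:
            d = res_vars[self.group_idx[idx]]          # (nb, s)
            sig = sg2 * kb.copy()
            ii = np.arange(kb.shape[1])
            sig[:, ii, ii] += d
            chol = np.linalg.cholesky(sig)
            logdet += 2.0 * np.sum(np.log(np.einsum("bii->bi", chol)))
            self._sinv.append(np.linalg.inv(sig))
        self._logdet = float(logdet)

    @property
    def logdet(self) -> float:
        return self._logdet

    def _blockwise(self, mats: list[np.ndarray], b: np.ndarray) -> np.ndarray:
        b = np.atleast_2d(b.T).T if b.ndim == 1 else b
        if b.shape[1] == 0:
            return np.empty_like(b, dtype=float)
        out = np.empty_like(b, dtype=float)
        for (idx, _), m in zip(self._by_size, mats):
            out[idx.ravel()] = np.einsum("bij,bjp->bip", m, b[idx]).reshape(
                -1, b.shape[1])
        return out

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Sigma^{-1} @ b (b may be a vector or n x p matrix)."""
        vec = b.ndim == 1
        out = self._blockwise(self._sinv, b[:, None] if vec else b)
        return out[:, 0] if vec else out

    def k_mul(self, b: np.ndarray) -> np.ndarray:
        """K @ b."""
        vec = b.ndim == 1
        kbs = [kb for _, kb in self._by_size]
        out = self._blockwise(kbs, b[:, None] if vec else b)
        return out[:, 0] if vec else out

    def diag_inv(self) -> np.ndarray:
        out = np.empty(self.n)
        for (idx, _), m in zip(self._by_size, self._sinv):
            out[idx.ravel()] = np.einsum("bii->bi", m).ravel()
        return out

    def trace_inv_k(self) -> float:
        return float(sum(np.sum(m * kb)
                         for (_, kb), m in zip(self._by_size, self._sinv)))


# ---------------------------------------------------------------------------
# model


class TelomereLMM:
    """Heteroskedastic linear mixed model with a kinship random effect.

    Parameters
    ----------
    endog : array (n,)
        Outcome (TL in bp, or a transformed outcome).
    exog : array (n, p)
        Fixed-effect design matrix; must include an intercept column if one
        is wanted and be full column rank.
    kinship : KinshipMatrix or array or sparse matrix
        PSD relatedness matrix aligned to the samples.
    groups : array (n,) of labels
        Residual-variance stratum of each sample (study-population group).
    """

    def __init__(self, endog, exog, kinship, groups,
                 exog_names: list[str] | None = None,
                 sample_ids: list[str] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        n = self.endog.shape[0]
        if self.exog.shape[0] != n:
            raise ValueError("endog/exog length mismatch")
        if isinstance(kinship, KinshipMatrix):
            kin = kinship.to_sparse()
        else:
            kin = sparse.csr_matrix(kinship)
        if kin.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        self.kinship = kin
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups length mismatch")
        self.group_labels, self.group_idx = np.unique(groups, return_inverse=True)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])]
        self.sample_ids = sample_ids
        self._check_rank()
        self._cov = BlockCovariance(kin, self.group_idx, len(self.group_labels))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       covariates: list[str], kinship: KinshipMatrix,
                       group_col: str, sample_col: str = "sample",
                       ) -> "TelomereLMM":
        """Build the model from a cohort table, aligning kinship to it.

        Categorical covariates are expanded to treatment-coded dummies; an
        intercept column is prepended.
        """
        samples = list(data[sample_col].astype(str))
        kin = kinship.reorder(samples)
        x_parts = [pd.Series(np.ones(len(data)), name="intercept")]
        for c in covariates:
            col = data[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=c, drop_first=True)
                x_parts.append(dummies.astype(float))
            else:
                x_parts.append(col.astype(float))
        x = pd.concat(x_parts, axis=1)
        return cls(endog=data[outcome].to_numpy(), exog=x.to_numpy(),
                   kinship=kin, groups=data[group_col].to_numpy(),
                   exog_names=list(x.columns), sample_ids=samples)

    def _check_rank(self) -> None:
        x = self.exog
        r = np.linalg.qr(x, mode="r")
        d = np.abs(np.diag(r))
        tol = max(x.shape) * np.finfo(float).eps * (d.max() if d.size else 1.0)
        bad = [self.exog_names[j] for j in np.flatnonzero(d <= tol)]
        if bad:
            raise ValueError(f"design matrix is rank deficient; "
                             f"aliased columns: {bad}")

    # ----------------------------------------------------------------- REML

    def _profile(self, sg2: float, res_vars: np.ndarray):
        """Solve the GLS system at the given variance components."""
        cov = self._cov
        cov.set_params(sg2, res_vars)
        x, y = self.exog, self.endog
        six = cov.solve(x)
        siy = cov.solve(y)
        xtsix = x.T @ six
        cf = cho_factor(xtsix)
        alpha = cho_solve(cf, x.T @ siy)
        py = siy - six @ alpha
        ypy = float(y @ py)
        sign, logdet_x = np.linalg.slogdet(xtsix)
        llf = -0.5 * (cov.logdet + logdet_x + ypy)
        return six, cf, alpha, py, llf

    def reml_loglike(self, sg2: float, res_vars: np.ndarray) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        return self._profile(sg2, np.asarray(res_vars, float))[4]

    def fit(self, maxiter: int = 100, tol: float = 1e-6,
            start: np.ndarray | None = None) -> "TelomereLMMResults":
        """Estimate variance components by average-information REML.

        Variances are floored at 1e-10 x total phenotypic variance; the
        update is step-halved whenever it would decrease the restricted
        likelihood.  Raises :class:`ConvergenceError` with the iteration
        trace if the relative likelihood change has not fallen below
        ``tol`` within ``maxiter`` iterations.
        """
        x, y = self.exog, self.endog
        n, p = x.shape
        ngrp = len(self.group_labels)
        ols_resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        var_total = float(np.var(ols_resid)) or float(np.var(y)) or 1.0
        floor = 1e-10 * var_total
        if start is None:
            theta = np.full(1 + ngrp, var_total / 2.0)
        else:
            theta = np.asarray(start, float).copy()
        theta = np.maximum(theta, floor)

        trace: list[dict] = []
        six, cf, alpha, py, llf = self._profile(theta[0], theta[1:])
        converged = False
        for it in range(maxiter):
            cov = self._cov
            # derivative directions t_k = V_k @ Py and V_k @ Sigma^{-1}X
            kpy = cov.k_mul(py)
            t_list = [kpy] + [np.where(self.group_idx == g, py, 0.0)
                              for g in range(ngrp)]
            diag_inv = cov.diag_inv()
            grad = np.empty(1 + ngrp)
            # trace(P V_k) = tr(S^-1 V_k) - tr((X'S^-1X)^-1 X'S^-1 V_k S^-1 X)
            ksix = cov.k_mul(six)
            tr_corr_k = float(np.trace(cho_solve(cf, six.T @ ksix)))
            grad[0] = -0.5 * ((cov.trace_inv_k() - tr_corr_k) - py @ kpy)
            for g in range(ngrp):
                mask = self.group_idx == g
                vk_six = np.where(mask[:, None], six, 0.0)
                tr_corr = float(np.trace(cho_solve(cf, six.T @ vk_six)))
                grad[1 + g] = -0.5 * ((diag_inv[mask].sum() - tr_corr)
                                      - py[mask] @ py[mask])
            # average information matrix: AI_jk = 0.5 t_j' P t_k
            pt = []
            for t in t_list:
                pt.append(cov.solve(t) - six @ cho_solve(cf, six.T @ t))
            ai = 0.5 * np.array([[tj @ ptk for ptk in pt] for tj in t_list])

            try:
                delta = np.linalg.solve(
                    ai + 1e-8 * np.eye(ai.shape[0]) * max(1.0, np.trace(ai)),
                    grad)
            except np.linalg.LinAlgError:
                delta = grad / max(1.0, np.abs(np.diag(ai)).max())

            step = 1.0
            while True:
                cand = np.maximum(theta + step * delta, floor)
                try:
                    prof = self._profile(cand[0], cand[1:])
                except np.linalg.LinAlgError:
                    prof = None
                if prof is not None and (prof[4] >= llf - 1e-10
                                         or step < 1e-4):
                    break
                step /= 2.0
                if step < 1e-6:
                    prof = self._profile(theta[0], theta[1:])
                    cand = theta
                    break
            new_llf = prof[4]
            trace.append({"iter": it, "llf": new_llf,
                          "theta": cand.copy(), "step": step})
            rel_change = abs(new_llf - llf) / max(1.0, abs(llf))
            theta, (six, cf, alpha, py, llf) = cand, prof
            if rel_change < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"AI-REML did not converge in {maxiter} iterations", trace)

        cov_params = cho_solve(cf, np.eye(p))
        return TelomereLMMResults(
            model=self, params=alpha, cov_params=cov_params,
            var_genetic=float(theta[0]),
            var_residual_by_group=pd.Series(
                theta[1:], index=[str(g) for g in self.group_labels]),
            llf=llf, converged=True, n_iter=len(trace),
            _six=six, _cf=cf, _py=py)


# ---------------------------------------------------------------------------
# results


@dataclass
class TelomereLMMResults:
    """Fitted null-model state: estimates, uncertainties, covariance solver."""

    model: TelomereLMM
    params: np.ndarray
    cov_params: np.ndarray
    var_genetic: float
    var_residual_by_group: pd.Series
    llf: float
    converged: bool
    n_iter: int
    _six: np.ndarray = None
    _cf: tuple = None
    _py: np.ndarray = None

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self.params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.model.exog_names)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / np.sqrt(np.diag(self.cov_params))
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)),
                         index=self.model.exog_names)

    @property
    def resid_marginal(self) -> np.ndarray:
        """y - X beta-hat (bp scale)."""
        return self.model.endog - self.model.exog @ self.params

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    @property
    def k_exog(self) -> int:
        return self.model.exog.shape[1]

    # covariance-operator contract -------------------------------------

    def solve_covariance(self, b: np.ndarray) -> np.ndarray:
        """Sigma^{-1} @ b at the fitted variance components."""
        return self.model._cov.solve(b)

    def project(self, b: np.ndarray) -> np.ndarray:
        """P @ b where P = S^-1 - S^-1 X (X'S^-1X)^-1 X'S^-1."""
        six = self._six
        sb = self.model._cov.solve(b)
        xtb = six.T @ b
        if b.ndim == 1:
            return sb - six @ cho_solve(self._cf, xtb)
        return sb - six @ cho_solve(self._cf, xtb)

    @property
    def py(self) -> np.ndarray:
        """P @ y, cached from the fit."""
        return self._py

    def summary(self) -> str:
        lines = ["Telomere-length linear mixed model (AI-REML)",
                 "=" * 60,
                 f"No. observations: {self.nobs}    "
                 f"groups: {len(self.var_residual_by_group)}    "
                 f"iterations: {self.n_iter}",
                 f"REML log-likelihood: {self.llf:.4f}",
                 "",
                 f"{'coef':>22} {'estimate':>12} {'std err':>10} {'P>|z|':>10}"]
        bse, pv = self.bse, self.pvalues
        for name in self.model.exog_names:
            lines.append(f"{name:>22} {self.fe_params[name]:>12.4f} "
                         f"{bse[name]:>10.4f} {pv[name]:>10.3g}")
        lines.append("")
        lines.append(f"{'var(genetic)':>22} {self.var_genetic:>12.4f}")
        for g, v in self.var_residual_by_group.items():
            lines.append(f"{'var(resid|' + str(g) + ')':>22} {v:>12.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# two-stage machinery


def fit_null_model(cohort: pd.DataFrame, outcome: str,
                   covariates: list[str], kinship: KinshipMatrix,
                   group_col: str, sample_col: str = "sample",
                   **fit_kwargs) -> TelomereLMMResults:
    """Fit the Stage-1 null mixed model from a cohort table."""
    model = TelomereLMM.from_dataframe(cohort, outcome, covariates, kinship,
                                       group_col, sample_col)
    return model.fit(**fit_kwargs)


def two_stage_transform(fit: TelomereLMMResults) -> np.ndarray:
    """Rank-inverse-normal transform of the marginal residuals, rescaled.

    Ranks use the Blom offset (r - 3/8)/(n + 1/4) with average ranks for
    ties; the normal quantiles are standardized by their own sample SD and
    multiplied by the sample SD (n-1 denominator) of the untransformed
    residuals, so the transformed outcome keeps bp units and exactly the
    residuals' spread — downstream effect sizes remain interpretable.
    """
    if not fit.converged:
        raise ValueError("stage-1 fit did not converge")
    r = fit.resid_marginal
    n = r.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for the rank transform")
    ranks = stats.rankdata(r, method="average")
    quantiles = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return quantiles / np.std(quantiles, ddof=1) * np.std(r, ddof=1)


def fit_stage2(fit1: TelomereLMMResults,
               extra_fixed: np.ndarray | None = None,
               extra_names: list[str] | None = None,
               maxiter: int = 100, tol: float = 1e-6) -> TelomereLMMResults:
    """Refit the identical model on the transformed Stage-1 residuals.

    ``extra_fixed`` (n x q genotype columns) supports conditional and joint
    models; variance components are re-estimated, not carried over.
    """
    model1 = fit1.model
    y2 = two_stage_transform(fit1)
    x = model1.exog
    names = list(model1.exog_names)
    if extra_fixed is not None:
        extra_fixed = np.atleast_2d(np.asarray(extra_fixed, float))
        if extra_fixed.shape[0] != x.shape[0]:
            extra_fixed = extra_fixed.T
        x = np.column_stack([x, extra_fixed])
        q = extra_fixed.shape[1]
        names += (list(extra_names) if extra_names is not None
                  else [f"geno{j}" for j in range(q)])
    model2 = TelomereLMM(endog=y2, exog=x, kinship=model1.kinship,
                         groups=model1.group_labels[model1.group_idx],
                         exog_names=names, sample_ids=model1.sample_ids)
    return model2.fit(maxiter=maxiter, tol=tol)


class TwoStageLMM:
    """Fully adjusted two-stage mixed model bound to a cohort table.

    ``fit()`` runs Stage 1 on the raw outcome, transforms the residuals,
    and runs Stage 2 on the transformed outcome.  ``extra_fixed`` columns
    (conditioning genotypes) enter both stages; ``stage2_fixed`` columns
    (joint-model sentinels) enter Stage 2 only.
    """

    def __init__(self, cohort: pd.DataFrame, outcome: str,
                 covariates: list[str], kinship: KinshipMatrix,
                 group_col: str, sample_col: str = "sample"):
        self.cohort = cohort.reset_index(drop=True)
        self.outcome = outcome
        self.covariates = list(covariates)
        self.kinship = kinship
        self.group_col = group_col
        self.sample_col = sample_col

    @property
    def samples(self) -> list[str]:
        return list(self.cohort[self.sample_col].astype(str))

    def fit(self, extra_fixed: np.ndarray | None = None,
            extra_names: list[str] | None = None,
            stage2_fixed: np.ndarray | None = None,
            stage2_names: list[str] | None = None,
            maxiter: int = 100, tol: float = 1e-6,
            ) -> tuple[TelomereLMMResults, TelomereLMMResults]:
        model1 = TelomereLMM.from_dataframe(
            self.cohort, self.outcome, self.covariates, self.kinship,
            self.group_col, self.sample_col)
        if extra_fixed is not None:
            extra_fixed = np.atleast_2d(np.asarray(extra_fixed, float))
            if extra_fixed.shape[0] != len(self.cohort):
                extra_fixed = extra_fixed.T
            q = extra_fixed.shape[1]
            names = (list(extra_names) if extra_names is not None
                     else [f"cond{j}" for j in range(q)])
            model1 = TelomereLMM(
                endog=model1.endog,
                exog=np.column_stack([model1.exog, extra_fixed]),
                kinship=model1.kinship,
                groups=self.cohort[self.group_col].to_numpy(),
                exog_names=model1.exog_names + names,
                sample_ids=model1.sample_ids)
        fit1 = model1.fit(maxiter=maxiter, tol=tol)
        fit2 = fit_stage2(fit1, extra_fixed=stage2_fixed,
                          extra_names=stage2_names,
                          maxiter=maxiter, tol=tol)
        return fit1, fit2
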