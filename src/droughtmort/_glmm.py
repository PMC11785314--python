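"""Binomial mixed model with a single Gaussian random intercept.

Supports the logit and complementary log-log links with frequency-style
case weights.  For a fixed random-effect SD the penalised likelihood is
maximised by Fisher scoring (penalised IRLS) using the Schur complement
of the block-structured working system — the random-intercept block is
diagonal, so each iteration costs one dense p x p solve.  The SD itself
is chosen by maximising the Laplace-approximate marginal likelihood
(the glmmTMB approach for this model family).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .errors import ValidationError

__all__ = ["BinomialMixedGLM"]

_ETA_CLIP = 30.0


def _link_funcs(link):
    if link == "logit":
        def mu_of(eta):
            return 1.0 / (1.0 + np.exp(-eta))

        def dmu(eta):
            m = mu_of(eta)
            return m * (1.0 - m)
    elif link == "cloglog":
        def mu_of(eta):
            return 1.0 - np.exp(-np.exp(eta))

        def dmu(eta):
            return np.exp(eta - np.exp(eta))
    else:
        raise ValidationError(f"unknown link {link!r}")
    return mu_of, dmu


class BinomialMixedGLM:
    """Weighted binomial GLM(M) with logit or cloglog link.

    After ``fit``: ``params_``, ``se_``, ``re_sd_``, ``ranef_``,
    ``loglik_`` (Laplace marginal when a random intercept is present),
    ``converged_``, ``flags_``.
    """

    def __init__(self, link: str = "logit", re_sd_bounds=(0.01, 3.0),
                 tol: float = 1e-9, max_iter: int = 100):
        self.link = link
        self.re_sd_bounds = re_sd_bounds
        self.tol = tol
        self.max_iter = max_iter

    def _pirls(self, X, y, w, g, q, sigma, beta0=None, b0=None):
        """Penalised IRLS at fixed sigma; returns beta, b, curvature pieces."""
        mu_of, dmu = _link_funcs(self.link)
        p = X.shape[1]
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        b = np.zeros(q) if b0 is None else b0.copy()
        pen = 0.0 if q == 0 else 1.0 / sigma**2

        def penalized_ll(beta, b):
            eta = np.clip(X @ beta + (b[g] if q else 0.0), -_ETA_CLIP, _ETA_CLIP)
            mu = np.clip(mu_of(eta), 1e-12, 1.0 - 1e-12)
            ll = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
            return ll - 0.5 * pen * float(b @ b)

        obj = penalized_ll(beta, b)
        for it in range(self.max_iter):
            eta = np.clip(X @ beta + (b[g] if q else 0.0), -_ETA_CLIP, _ETA_CLIP)
            mu = np.clip(mu_of(eta), 1e-12, 1.0 - 1e-12)
            d = np.maximum(dmu(eta), 1e-12)
            W = w * d * d / (mu * (1.0 - mu))
            score_eta = w * (y - mu) * d / (mu * (1.0 - mu))
            # working gradient / information in (beta, b)
            gb = X.T @ score_eta
            XtWX = X.T @ (X * W[:, None])
            if q:
                gg = np.bincount(g, weights=score_eta, minlength=q) - pen * b
                Dg = np.bincount(g, weights=W, minlength=q) + pen
                XtWZ = np.zeros((q, p))
                np.add.at(XtWZ, g, X * W[:, None])
                # Schur complement solve
                Sinv = 1.0 / Dg
                S = XtWX - XtWZ.T @ (XtWZ * Sinv[:, None])
                rhs = gb - XtWZ.T @ (gg * Sinv)
                try:
                    dbeta = np.linalg.solve(S, rhs)
                except np.linalg.LinAlgError:
                    dbeta = np.linalg.lstsq(S, rhs, rcond=None)[0]
                db = Sinv * (gg - XtWZ @ dbeta)
            else:
                try:
                    dbeta = np.linalg.solve(XtWX, gb)
                except np.linalg.LinAlgError:
                    dbeta = np.linalg.lstsq(XtWX, gb, rcond=None)[0]
                db = b
            scale = 1.0
            for _ in range(30):
                nb = beta + scale * dbeta
                nbb = b + scale * db if q else b
                nobj = penalized_ll(nb, nbb)
                if np.isfinite(nobj) and nobj >= obj - 1e-12:
                    break
                scale *= 0.5
            beta, b = nb, nbb
            if abs(nobj - obj) < self.tol * (abs(nobj) + 1.0):
                obj = nobj
                break
            obj = nobj
        # final curvature at the optimum
        eta = np.clip(X @ beta + (b[g] if q else 0.0), -_ETA_CLIP, _ETA_CLIP)
        mu = np.clip(mu_of(eta), 1e-12, 1.0 - 1e-12)
        d = np.maximum(dmu(eta), 1e-12)
        W = w * d * d / (mu * (1.0 - mu))
        XtWX = X.T @ (X * W[:, None])
        if q:
            Dg_raw = np.bincount(g, weights=W, minlength=q)
            XtWZ = np.zeros((q, p))
            np.add.at(XtWZ, g, X * W[:, None])
        else:
            Dg_raw, XtWZ = None, None
        ll = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
        return beta, b, ll, obj, XtWX, XtWZ, Dg_raw

    def fit(self, X, y, weights=None, groups=None, re_sd=None, names=None):
        """Fit; ``groups=None`` gives the plain weighted GLM."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if groups is not None:
            codes, g = np.unique(np.asarray(groups), return_inverse=True)
            q = codes.size
        else:
            codes, g, q = None, None, 0
        self.names_ = list(names) if names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        self.flags_ = []

        if q == 0:
            beta, b, ll, obj, XtWX, _, _ = self._pirls(X, y, w, g, 0, None)
            self.re_sd_ = None
            self.ranef_ = None
            cov = np.linalg.pinv(XtWX)
            self.loglik_ = ll
        else:
            warm = [None, None]

            def neg_marginal(log_sigma):
                sigma = float(np.exp(log_sigma))
                beta, b, ll, obj, XtWX, XtWZ, Dg = self._pirls(
                    X, y, w, g, q, sigma, warm[0], warm[1]
                )
                warm[0], warm[1] = beta, b
                logdet = float(np.log1p(sigma**2 * Dg).sum())
                return -(obj - 0.5 * logdet)

            lo, hi = np.log(self.re_sd_bounds[0]), np.log(self.re_sd_bounds[1])
            if re_sd is not None:
                sigma = float(re_sd)
            else:
                res = optimize.minimize_scalar(
                    neg_marginal, bounds=(lo, hi), method="bounded",
                    options={"xatol": 0.02, "maxiter": 25},
                )
                sigma = float(np.exp(res.x))
            beta, b, ll, obj, XtWX, XtWZ, Dg = self._pirls(
                X, y, w, g, q, sigma, warm[0], warm[1]
            )
            self.re_sd_ = sigma
            if re_sd is None and abs(np.log(sigma) - lo) < 0.03:
                self.re_sd_ = 0.0
                self.flags_.append("random-effect SD at lower bound (treated as ~0)")
            self.ranef_ = dict(zip(codes, b))
            Sinv = 1.0 / (Dg + 1.0 / sigma**2)
            cov = np.linalg.pinv(XtWX - XtWZ.T @ (XtWZ * Sinv[:, None]))
            self.loglik_ = obj - 0.5 * float(np.log1p(sigma**2 * Dg).sum())

        self.params_ = beta
        self.se_ = np.sqrt(np.maximum(np.diag(cov), 0.0))
        self.cov_ = cov
        self.converged_ = True
        if np.any(np.abs(beta) > 10.0):
            # typically an event-free nuisance category drifting off;
            # the affected CI is unreliable, the fit overall still usable
            self.flags_.append("suspected separation: |coef| > 10")
        self.n_obs_ = n
        return self
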