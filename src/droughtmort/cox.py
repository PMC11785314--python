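"""Weighted time-dependent Cox model with an optional Gaussian frailty.

The estimator maximises the weighted partial likelihood of a
counting-process table whose rows are unit intervals ``[t, t+1)`` on a
monthly clock; the covariate values of a row apply at the event time
``t`` and ties (which are heavy on a monthly grid) are handled by the
Efron approximation by default.  A cluster random intercept ("frailty")
on the log-hazard scale is fitted by penalised partial likelihood:
for a fixed random-effect SD ``sigma`` the penalised objective

    pl(beta, b) - ||b||^2 / (2 sigma^2)

is maximised jointly by Newton-Raphson (the machinery of coxme), and
``sigma`` itself is chosen by maximising the Laplace-approximate
integrated partial likelihood.  Sampling weights enter as case weights
in the likelihood.

Only rows whose start time carries at least one event contribute to the
partial likelihood, so rows covering event-free periods (e.g. gestation,
when the clock starts at conception) are dropped internally.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .errors import ValidationError

__all__ = ["CoxTimeVaryingFrailty"]


def _prepare(t, event):
    t = np.asarray(t)
    event = np.asarray(event).astype(bool)
    if event.sum() == 0:
        raise ValidationError("zero events: cannot fit a Cox model")
    event_times = np.unique(t[event])
    keep = np.isin(t, event_times)
    return keep, event_times


class _CoxData:
    """Preprocessed, time-sliced view of the counting-process table."""

    def __init__(self, X, t, event, weights, groups):
        keep, event_times = _prepare(t, event)
        order = np.argsort(t[keep], kind="stable")
        idx = np.flatnonzero(keep)[order]
        self.X = np.ascontiguousarray(X[idx], dtype=float)
        self.t = np.asarray(t)[idx]
        self.event = np.asarray(event)[idx].astype(bool)
        self.w = np.asarray(weights)[idx].astype(float)
        self.groups = None if groups is None else np.asarray(groups)[idx]
        self.row_index = idx
        self.event_times = event_times
        bounds = np.searchsorted(self.t, event_times, side="left")
        self.slices = list(zip(bounds, np.append(bounds[1:], self.t.size)))
        self.p = self.X.shape[1]
        if self.groups is not None:
            self.group_codes, self.g = np.unique(self.groups, return_inverse=True)
            self.q = self.group_codes.size
        else:
            self.g = None
            self.q = 0


class CoxTimeVaryingFrailty:
    """Time-dependent Cox regression with optional Gaussian cluster frailty.

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Tie approximation for the heavily tied monthly event times.
    penalizer_bounds : (float, float)
        Search interval for the frailty SD when it is estimated.
    tol, max_iter : Newton-Raphson controls.

    After ``fit``: ``params_`` (log hazard ratios), ``se_``,
    ``frailty_sd_``, ``frailty_``, ``loglik_``, ``converged_``,
    ``n_events_``, ``flags_`` (e.g. suspected separation).
    """

    def __init__(self, ties: str = "efron", penalizer_bounds=(0.01, 3.0),
                 tol: float = 1e-9, max_iter: int = 60):
        if ties not in ("efron", "breslow"):
            raise ValidationError(f"unknown tie method {ties!r}")
        self.ties = ties
        self.penalizer_bounds = penalizer_bounds
        self.tol = tol
        self.max_iter = max_iter

    # -- likelihood machinery ------------------------------------------

    def _accumulate(self, data: _CoxData, beta, b, want_hessian=True):
        """Negative quantities are not used; returns (loglik, grad, H).

        ``grad``/``H`` cover the stacked parameter (beta, b) without the
        frailty penalty.
        """
        p, q = data.p, data.q
        dim = p + q
        eta = data.X @ beta
        if q:
            eta = eta + b[data.g]
        eta = np.clip(eta, -200, 200)
        r = data.w * np.exp(eta)
        ll = 0.0
        grad = np.zeros(dim)
        H = np.zeros((dim, dim)) if want_hessian else None
        for (lo, hi), tau in zip(data.slices, data.event_times):
            sl = slice(lo, hi)
            Xs = data.X[sl]
            rs = r[sl]
            ev = data.event[sl]
            ws = data.w[sl]
            d_idx = np.flatnonzero(ev)
            d = d_idx.size
            W_D = ws[d_idx].sum()
            S0R = rs.sum()
            S1Rx = Xs.T @ rs
            S0D = rs[d_idx].sum()
            S1Dx = Xs[d_idx].T @ rs[d_idx]
            if q:
                gs = data.g[sl]
                S1Rg = np.bincount(gs, weights=rs, minlength=q)
                S1Dg = np.bincount(gs[d_idx], weights=rs[d_idx], minlength=q)
            ll += float((ws[d_idx] * eta[sl][d_idx]).sum())
            grad[:p] += Xs[d_idx].T @ ws[d_idx]
            if q:
                grad[p:] += np.bincount(gs[d_idx], weights=ws[d_idx], minlength=q)

            if self.ties == "breslow" or d == 1:
                fracs = np.zeros(1)
            else:
                fracs = np.arange(d) / d
            c_l = W_D / fracs.size
            den = S0R - fracs * S0D                        # (L,)
            ll -= float(c_l * np.log(den).sum())
            # mu_l rows: (L, dim)
            mu = np.empty((fracs.size, p + q))
            mu[:, :p] = (S1Rx[None, :] - fracs[:, None] * S1Dx[None, :]) / den[:, None]
            if q:
                mu[:, p:] = (S1Rg[None, :] - fracs[:, None] * S1Dg[None, :]) / den[:, None]
            grad -= c_l * mu.sum(axis=0)
            if want_hessian:
                A = float(c_l * (1.0 / den).sum())
                B = float(c_l * (fracs / den).sum())
                # S2 blocks
                Xw = Xs * rs[:, None]
                S2Rxx = Xs.T @ Xw
                XD = Xs[d_idx]
                S2Dxx = XD.T @ (XD * rs[d_idx][:, None])
                H[:p, :p] -= A * S2Rxx - B * S2Dxx
                if q:
                    S2Rxg = np.zeros((q, p))
                    np.add.at(S2Rxg, gs, Xw)
                    S2Dxg = np.zeros((q, p))
                    np.add.at(S2Dxg, gs[d_idx], XD * rs[d_idx][:, None])
                    blk = A * S2Rxg - B * S2Dxg
                    H[p:, :p] -= blk
                    H[:p, p:] -= blk.T
                    dg = A * S1Rg - B * S1Dg
                    H[p:, p:] -= np.diag(dg)
                Mc = mu * np.sqrt(c_l)
                H += Mc.T @ Mc
        return ll, grad, H

    def _newton(self, data: _CoxData, sigma, beta0=None, b0=None):
        p, q = data.p, data.q
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        b = np.zeros(q) if b0 is None else b0.copy()
        pen = 0.0 if sigma is None else 1.0 / sigma**2
        ll, grad, H = self._accumulate(data, beta, b)
        obj = ll - 0.5 * pen * (b @ b)
        for it in range(self.max_iter):
            g_pen = grad.copy()
            H_pen = -H
            if q:
                g_pen[p:] -= pen * b
                H_pen[p:, p:] += pen * np.eye(q)
            try:
                step = np.linalg.solve(H_pen, g_pen)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H_pen, g_pen, rcond=None)[0]
            scale = 1.0
            for _ in range(30):
                nb = beta + scale * step[:p]
                nbb = b + scale * step[p:] if q else b
                nll, ngrad, nH = self._accumulate(data, nb, nbb)
                nobj = nll - 0.5 * pen * (nbb @ nbb if q else 0.0)
                if np.isfinite(nobj) and nobj >= obj - 1e-12:
                    break
                scale *= 0.5
            beta, b = nb, (nbb if q else b)
            improved = nobj - obj
            ll, grad, H, obj = nll, ngrad, nH, nobj
            if abs(improved) < self.tol * (abs(obj) + 1.0):
                gn = grad.copy()
                if q:
                    gn[p:] -= pen * b
                if np.linalg.norm(gn) < 1e-4 * (1.0 + np.linalg.norm(beta)):
                    return beta, b, ll, obj, grad, H, True
        gn = grad.copy()
        if q:
            gn[p:] -= pen * b
        return beta, b, ll, obj, grad, H, np.linalg.norm(gn) < 1e-3

    def _laplace(self, data: _CoxData, sigma, warm):
        beta, b, ll, obj, grad, H, ok = self._newton(data, sigma, *warm)
        q, p = data.q, data.p
        Hbb = -H[p:, p:] + np.eye(q) / sigma**2
        sign, logdet = np.linalg.slogdet(Hbb)
        if sign <= 0:
            return -np.inf, (beta, b)
        ill = obj - 0.5 * logdet - q * np.log(sigma)
        return ill, (beta, b)

    # -- public API ----------------------------------------------------

    def fit(self, X, t, event, weights=None, groups=None, frailty_sd=None,
            names=None, robust: bool = False):
        """Fit the model.

        Parameters
        ----------
        X : (n, p) array of covariate values per person-month row.
        t : (n,) integer start time of each unit interval.
        event : (n,) 0/1 event flag (event at the end of the row's interval).
        weights : sampling weights (case weights); default 1.
        groups : cluster codes for the Gaussian frailty; None = no frailty.
        frailty_sd : fix the frailty SD instead of estimating it.
        robust : grouped sandwich variance (requires Breslow ties and no
            frailty; groups the score by ``groups`` if given).
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if weights is None:
            weights = np.ones(n)
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("weights must be positive")
        frail_groups = groups if frailty_sd is None or frailty_sd > 0 else None
        data = _CoxData(X, t, event, w, frail_groups if not robust else None)
        if robust and (self.ties != "breslow" or (frail_groups is not None)):
            raise ValidationError(
                "robust variance requires Breslow ties and no frailty"
            )

        self.names_ = list(names) if names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        p, q = data.p, data.q
        self.flags_ = []

        if q == 0:
            beta, b, ll, obj, grad, H, ok = self._newton(data, None)
            self.frailty_sd_ = None
            self.frailty_ = None
            H_pen = -H
        elif frailty_sd is not None:
            beta, b, ll, obj, grad, H, ok = self._newton(data, frailty_sd)
            self.frailty_sd_ = float(frailty_sd)
            self.frailty_ = dict(zip(data.group_codes, b))
            H_pen = -H
            H_pen[p:, p:] += np.eye(q) / frailty_sd**2
        else:
            warm = [None, None]

            def neg_ill(log_sigma):
                ill, sol = self._laplace(data, np.exp(log_sigma), warm)
                warm[0], warm[1] = sol
                return -ill

            lo, hi = np.log(self.penalizer_bounds[0]), np.log(self.penalizer_bounds[1])
            res = optimize.minimize_scalar(
                neg_ill, bounds=(lo, hi), method="bounded",
                options={"xatol": 0.02, "maxiter": 25},
            )
            sigma = float(np.exp(res.x))
            beta, b, ll, obj, grad, H, ok = self._newton(data, sigma, *warm)
            self.frailty_sd_ = sigma
            self.frailty_ = dict(zip(data.group_codes, b))
            H_pen = -H
            H_pen[p:, p:] += np.eye(q) / sigma**2
            if abs(res.x - lo) < 0.03:
                self.frailty_sd_ = 0.0
                self.flags_.append("frailty SD at lower bound (treated as ~0)")

        cov = np.linalg.pinv(H_pen)
        self.params_ = beta
        self.se_ = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
        if robust:
            self.se_ = self._robust_se(data, beta, groups)
        self.loglik_ = float(ll)
        self.converged_ = bool(ok)
        self.n_events_ = int(data.event.sum())
        self.n_obs_ = n
        if np.any(np.abs(beta) > 8.0):
            self.flags_.append("suspected separation: |coef| > 8")
        if not ok:
            self.flags_.append("Newton-Raphson did not meet the gradient tolerance")
        return self

    def _robust_se(self, data: _CoxData, beta, groups):
        """Grouped sandwich variance via Breslow score residuals."""
        eta = np.clip(data.X @ beta, -200, 200)
        r = data.w * np.exp(eta)
        resid = np.zeros_like(data.X)
        for (lo, hi), tau in zip(data.slices, data.event_times):
            sl = slice(lo, hi)
            rs = r[sl]
            ws = data.w[sl]
            ev = data.event[sl]
            S0 = rs.sum()
            mu = (data.X[sl].T @ rs) / S0
            dlam = ws[ev].sum() / S0
            resid[sl] = (data.X[sl] - mu) * (
                ws * ev.astype(float) - rs * dlam
            )[:, None]
        if groups is None:
            g = np.arange(resid.shape[0])
        else:
            g = np.unique(np.asarray(groups)[data.row_index], return_inverse=True)[1]
        U = np.zeros((g.max() + 1, data.p))
        np.add.at(U, g, resid)
        _, _, H = self._accumulate(data, beta, np.zeros(0))
        A = np.linalg.pinv(-H)
        V = A @ (U.T @ U) @ A
        return np.sqrt(np.maximum(np.diag(V), 0.0))
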