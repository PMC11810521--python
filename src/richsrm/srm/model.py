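"""Log-posterior and gradient for the SRM, on an unconstrained vector.

Parameterisation (non-centred):

* fixed effects ``beta_self`` (multinomial self-cell) and ``beta``
  (dyad-cell) with Normal(0, prior.fixed_sd) priors;
* sender/receiver (or keep/receiver) effects: for focal individuals
  ``s_i = sigma_s * z_s_i`` and
  ``r_i = sigma_r * (rho_gr * z_s_i + sqrt(1 - rho_gr^2) * z_r_i)``
  (so cor(s_i, r_i) = rho_gr, the generalised-reciprocity correlation);
  non-focal individuals have only ``r_j = sigma_r * z_r_j``;
* dyad effects per unordered pair {i, j}: ``d_ij = sigma_d * z1`` and
  ``d_ji = sigma_d * (rho_dd * z1 + sqrt(1 - rho_dd^2) * z2)``
  (dyadic reciprocity);
* scales ``sigma = exp(log_sigma)`` with half-Normal(0, prior.sigma_sd)
  priors (log-scale Jacobian included);
* correlations ``rho = tanh(u)`` with LKJ(eta) priors on the implied 2x2
  correlation matrices (tanh Jacobian included).

All gradients are hand-derived and verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

from ..network_data import AllocationSet, BinaryLayer, ValidationError
from .design import SRMDesign
from .spec import SRMParameters


class ParamLayout:
    """Named slices into the flat unconstrained parameter vector."""

    def __init__(self, design: SRMDesign):
        blocks: list[tuple[str, int]] = []
        blocks.append(("beta_self", len(design.s_names)))
        blocks.append(("beta", len(design.x_names)))
        blocks.append(("z_s", design.n_f))
        blocks.append(("z_r", design.n))
        blocks.append(("log_sigma_s", 1))
        blocks.append(("log_sigma_r", 1))
        blocks.append(("u_gr", 1))
        if design.spec.include_dyad_effects:
            m = len(design.pair_i)
            blocks.append(("z_d1", m))
            blocks.append(("z_d2", m))
            blocks.append(("log_sigma_d", 1))
            blocks.append(("u_dd", 1))
        self.slices: dict[str, slice] = {}
        start = 0
        for name, size in blocks:
            self.slices[name] = slice(start, start + size)
            start += size
        self.size = start

    def get(self, vec: np.ndarray, name: str) -> np.ndarray:
        return vec[self.slices[name]]


def linear_predictor(
    design: SRMDesign,
    params: SRMParameters,
    s: np.ndarray | None = None,
    r: np.ndarray | None = None,
    d: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Assemble the per-cell scores for given parameter values.

    ``s`` (length n_f), ``r`` (length n) and ``d`` (n_f x n) are realised
    random effects; omitted effects are zero.  Returns a dict with
    ``"eta"`` — the (n_f, n) dyad-cell score grid (self cells carry the
    self/keep score for the multinomial family and are masked out for the
    bernoulli family) — plus the ``"mask"`` of valid alter cells.
    """
    beta_self, beta = design.fixed_vector(dict(params.fixed))
    eta = np.tensordot(beta, design.X, axes=([0], [0]))
    if s is not None:
        eta += np.asarray(s, dtype=float)[:, None] * design.mask
    if r is not None:
        eta += np.asarray(r, dtype=float)[None, :] * design.mask
    if d is not None:
        eta += np.asarray(d, dtype=float) * design.mask
    if design.spec.outcome_kind == "multinomial":
        eta_self = beta_self @ design.S
        if s is not None:
            eta_self = eta_self + np.asarray(s, dtype=float)
        rows = np.arange(design.n_f)
        eta[rows, design.focal_idx] = eta_self
    return {"eta": eta, "mask": design.mask}


class SRMModel:
    """Joint log-posterior (and gradient) of one SRM fit."""

    def __init__(self, design: SRMDesign, outcome):
        self.design = design
        self.layout = ParamLayout(design)
        spec = design.spec
        d = design
        if spec.outcome_kind == "bernoulli":
            if not isinstance(outcome, BinaryLayer):
                raise ValidationError("bernoulli SRM needs a BinaryLayer outcome")
            if outcome.focal_ids != d.focal_ids:
                raise ValidationError("outcome focal set differs from design")
            self.Y = outcome.adjacency[d.focal_idx, :].astype(float)
            vals = self.Y[d.mask]
            if vals.min() == vals.max():
                raise ValidationError(
                    f"layer {outcome.name!r} has zero variance in the outcome; "
                    "refusing a degenerate fit"
                )
            self.counts = None
        else:
            if not isinstance(outcome, AllocationSet):
                raise ValidationError("multinomial SRM needs an AllocationSet outcome")
            if outcome.focal_ids != d.focal_ids:
                raise ValidationError("outcome focal set differs from design")
            self.counts = outcome.count_matrix().astype(float)
            self.budgets = self.counts.sum(axis=1)
            off_self = self.counts[d.mask]
            if off_self.max() == 0:
                raise ValidationError(
                    f"allocation set {outcome.game!r} has no coins placed on "
                    "alters; refusing a degenerate fit"
                )
            # multinomial coefficient: constant in the parameters
            self.log_coef = float(
                (gammaln(self.budgets + 1.0) - gammaln(self.counts + 1.0).sum(axis=1)).sum()
            )
            self.Y = None
        # focal positions within the roster-length receiver block
        self.focal_pos = d.focal_idx
        self.rows = np.arange(d.n_f)
        self.prior = spec.priors
        # flattened design and float mask: hot-loop precomputations
        self.X2 = d.X.reshape(len(d.x_names), -1)
        self.maskf = d.mask.astype(float)

    # ---- transforms ------------------------------------------------------
    def _unpack(self, vec: np.ndarray):
        L, d = self.layout, self.design
        beta_self = L.get(vec, "beta_self")
        beta = L.get(vec, "beta")
        z_s = L.get(vec, "z_s")
        z_r = L.get(vec, "z_r")
        log_sig_s = L.get(vec, "log_sigma_s")[0]
        log_sig_r = L.get(vec, "log_sigma_r")[0]
        u_gr = L.get(vec, "u_gr")[0]
        out = dict(
            beta_self=beta_self, beta=beta, z_s=z_s, z_r=z_r,
            log_sig_s=log_sig_s, log_sig_r=log_sig_r, u_gr=u_gr,
        )
        if d.spec.include_dyad_effects:
            out.update(
                z_d1=L.get(vec, "z_d1"),
                z_d2=L.get(vec, "z_d2"),
                log_sig_d=L.get(vec, "log_sigma_d")[0],
                u_dd=L.get(vec, "u_dd")[0],
            )
        return out

    def logp_and_grad(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        L, d = self.layout, self.design
        p = self._unpack(vec)
        sig_s, sig_r = np.exp(p["log_sig_s"]), np.exp(p["log_sig_r"])
        rho = np.tanh(p["u_gr"])
        # stable identities: sqrt(1 - tanh^2 u) = sech u, rho / c = sinh u
        c = 1.0 / np.cosh(p["u_gr"])

        s = sig_s * p["z_s"]  # length n_f
        z_s_full = np.zeros(d.n)
        z_s_full[self.focal_pos] = p["z_s"]
        a_vec = np.where(d.is_focal, rho, 0.0)
        c_vec = np.where(d.is_focal, c, 1.0)
        r = sig_r * (a_vec * z_s_full + c_vec * p["z_r"])  # length n

        eta = (p["beta"] @ self.X2).reshape(d.n_f, d.n)
        if d.spec.outcome_kind == "bernoulli":
            eta += s[:, None] * self.maskf
        # receiver effects act on alter cells only
        eta += r[None, :] * self.maskf

        if d.spec.include_dyad_effects:
            sig_d = np.exp(p["log_sig_d"])
            rho_d = np.tanh(p["u_dd"])
            c_d = 1.0 / np.cosh(p["u_dd"])
            D = np.zeros((d.n, d.n))
            d_ij = sig_d * p["z_d1"]
            d_ji = sig_d * (rho_d * p["z_d1"] + c_d * p["z_d2"])
            D[d.pair_i, d.pair_j] = d_ij
            D[d.pair_j, d.pair_i] = d_ji
            eta += D[self.focal_pos, :] * self.maskf

        if d.spec.outcome_kind == "multinomial":
            eta_self = p["beta_self"] @ d.S + s
            eta[self.rows, self.focal_pos] = eta_self
            # row-wise log-softmax
            m = eta.max(axis=1, keepdims=True)
            ex = np.exp(eta - m)
            Z = ex.sum(axis=1, keepdims=True)
            log_p = (eta - m) - np.log(Z)
            ll = self.log_coef + float((self.counts * log_p).sum())
            G = self.counts - self.budgets[:, None] * (ex / Z)
        else:
            # stable bernoulli log-lik and residual:
            #   y*eta - log(1 + exp(eta)) per cell
            pm = expit(eta)
            ll_cells = self.Y * eta - np.logaddexp(0.0, eta)
            ll = float((ll_cells * self.maskf).sum())
            G = (self.Y - pm) * self.maskf

        # split gradient pieces
        if d.spec.outcome_kind == "multinomial":
            g_self = G[self.rows, self.focal_pos].copy()
            G_alter = G.copy()
            G_alter[self.rows, self.focal_pos] = 0.0
        else:
            g_self = G.sum(axis=1)  # d ll / d s_i (focal row sums)
            G_alter = G
        g_r = G_alter.sum(axis=0)  # d ll / d r_j

        grad = np.zeros(L.size)
        fs2 = self.prior.fixed_sd ** 2
        ss2 = self.prior.sigma_sd ** 2

        # fixed effects
        if len(d.s_names):
            grad[L.slices["beta_self"]] = d.S @ g_self - p["beta_self"] / fs2
        grad[L.slices["beta"]] = (
            self.X2
            @ (G_alter if d.spec.outcome_kind == "multinomial" else G).ravel()
            - p["beta"] / fs2
        )

        # sender/receiver block
        g_r_focal = g_r[self.focal_pos]
        grad[L.slices["z_s"]] = (
            g_self * sig_s + g_r_focal * sig_r * rho - p["z_s"]
        )
        grad[L.slices["z_r"]] = g_r * sig_r * c_vec - p["z_r"]
        grad[L.slices["log_sigma_s"]] = (
            sig_s * float(g_self @ p["z_s"]) + 1.0 - sig_s * sig_s / ss2
        )
        grad[L.slices["log_sigma_r"]] = float(g_r @ r) + 1.0 - sig_r * sig_r / ss2
        dr_drho = sig_r * np.where(
            d.is_focal, z_s_full - np.sinh(p["u_gr"]) * p["z_r"], 0.0
        )
        lkj = self.prior.lkj_eta  # prior (eta-1) plus tanh Jacobian gives eta
        grad[L.slices["u_gr"]] = (1.0 - rho * rho) * float(g_r @ dr_drho) - 2.0 * lkj * rho

        # dyad block
        if d.spec.include_dyad_effects:
            Gn = np.zeros((d.n, d.n))
            Gn[self.focal_pos, :] = G_alter if d.spec.outcome_kind == "multinomial" else G
            g_ij = Gn[d.pair_i, d.pair_j]
            g_ji = Gn[d.pair_j, d.pair_i]
            grad[L.slices["z_d1"]] = sig_d * (g_ij + rho_d * g_ji) - p["z_d1"]
            grad[L.slices["z_d2"]] = sig_d * c_d * g_ji - p["z_d2"]
            grad[L.slices["log_sigma_d"]] = (
                float(g_ij @ d_ij + g_ji @ d_ji) + 1.0 - sig_d * sig_d / ss2
            )
            dd_drho = sig_d * (p["z_d1"] - np.sinh(p["u_dd"]) * p["z_d2"])
            grad[L.slices["u_dd"]] = (
                (1.0 - rho_d * rho_d) * float(g_ji @ dd_drho) - 2.0 * lkj * rho_d
            )

        # priors on the log-density
        logp = ll
        logp += -0.5 * float(p["beta_self"] @ p["beta_self"]) / fs2
        logp += -0.5 * float(p["beta"] @ p["beta"]) / fs2
        logp += -0.5 * float(p["z_s"] @ p["z_s"]) - 0.5 * float(p["z_r"] @ p["z_r"])
        logp += -0.5 * sig_s * sig_s / ss2 + p["log_sig_s"]
        logp += -0.5 * sig_r * sig_r / ss2 + p["log_sig_r"]
        logp += -2.0 * lkj * np.log(np.cosh(p["u_gr"]))
        if d.spec.include_dyad_effects:
            logp += -0.5 * float(p["z_d1"] @ p["z_d1"]) - 0.5 * float(
                p["z_d2"] @ p["z_d2"]
            )
            logp += -0.5 * sig_d * sig_d / ss2 + p["log_sig_d"]
            logp += -2.0 * lkj * np.log(np.cosh(p["u_dd"]))
        return logp, grad

    def logp(self, vec: np.ndarray) -> float:
        return self.logp_and_grad(vec)[0]
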