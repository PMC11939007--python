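"""Balanced Cox-mixture T-learner for individualized survival treatment effects.

The model (BIME) couples three ideas:

* **T-learner**: two arm-specific risk networks predict survival under each
  surgery; the individual treatment effect (ITE) is the difference of the
  arm-specific times-at-risk (TaR), the first time predicted survival falls
  to the mortality threshold (default 10% survival), capped at the analysis
  horizon (default 120 months).
* **Representation balancing**: both risk networks read a shared latent
  encoding of the covariates, and a debiased entropic-optimal-transport
  (p-Wasserstein) penalty pushes the latent distributions of the two arms
  together, mitigating confounded treatment assignment.
* **Cox mixture**: within each arm, K latent components each carry their own
  log-hazard head and Breslow baseline; a gating network assigns patients to
  components.  Proportional hazards is assumed only within a component, so
  the model tolerates crossing hazards across patient subgroups.  Training
  uses Monte Carlo EM: the E-step samples component assignments from the
  posterior (gate x component survival likelihood), the M-step takes
  gradient steps with the sampled assignments fixed.

The per-batch training objective is

    total = q * lCox(arm 0) + (1 - q) * lCox(arm 1) + alpha * IPM + Q(arm 0) + Q(arm 1)

with ``q`` the fraction of the minibatch in the control arm (0 = NSM),
``lCox`` the mixture-marginal negative Cox partial log-likelihood (averaged
per event), ``IPM`` the Sinkhorn divergence between the arms' latent
batches, and ``Q`` the Monte-Carlo E-step loss (gating log-probability plus
component-conditional Cox likelihood at the sampled assignments).
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator

from ._nn import MLP, Adam
from ._sinkhorn import sinkhorn_divergence
from .causal import SurvivalCurve

logger = logging.getLogger(__name__)

__all__ = [
    "BimeRecommender", "BimeLossParts", "cox_neg_partial_loglik",
    "time_at_risk", "mixture_log_hazard",
]


# ---------------------------------------------------------------------------
# loss primitives


def cox_neg_partial_loglik(eta, time, event, weights=None, return_grad=False):
    """Breslow negative Cox partial log-likelihood, averaged per event.

    Invariant under adding a constant to ``eta``.  Optional case weights
    (used for posterior-weighted component likelihoods).  A batch with no
    events contributes 0 with a warning.
    """
    eta = np.asarray(eta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    w = np.ones(len(eta)) if weights is None else np.asarray(weights, float)
    D = float((w * event).sum())
    if D <= 0:
        warnings.warn("no (weighted) events in batch; Cox loss contributes 0")
        return (0.0, np.zeros_like(eta)) if return_grad else 0.0

    order = np.argsort(time, kind="stable")
    t_s, e_s, w_s, eta_s = time[order], event[order], w[order], eta[order]
    rexp = w_s * np.exp(eta_s)
    # risk sums: subjects with t >= u  (suffix sums; ties handled via block start)
    suffix = np.cumsum(rexp[::-1])[::-1]
    uniq, first_idx = np.unique(t_s, return_index=True)
    s0_by_time = suffix[first_idx]
    # weighted deaths per unique time
    d_by_time = np.zeros(len(uniq))
    ev_idx = np.searchsorted(uniq, t_s)
    np.add.at(d_by_time, ev_idx, w_s * e_s)
    has_event = d_by_time > 0
    ll = float((w_s * e_s * eta_s).sum() - (d_by_time[has_event] * np.log(s0_by_time[has_event])).sum())
    nll = -ll / D
    if not return_grad:
        return nll
    # grad wrt eta: (-w_i E_i + w_i exp(eta_i) * sum_{event u <= t_i} d_u / S0_u) / D
    factor = np.where(has_event, d_by_time / s0_by_time, 0.0)
    cfac = np.cumsum(factor)
    upto = np.searchsorted(uniq, t_s, side="right") - 1
    g_s = (-w_s * e_s + rexp * cfac[np.clip(upto, 0, None)]) / D
    g_s[upto < 0] = (-w_s * e_s)[upto < 0] / D
    grad = np.empty_like(g_s)
    grad[order] = g_s
    return nll, grad


def mixture_log_hazard(gate_logits, f):
    """Marginal log-hazard of a Cox mixture.

    ``eta = log sum_k g_k exp(f_k)`` with gates ``g = softmax(gate_logits)``.
    Returns ``(eta_marginal, f, gates)``.
    """
    log_g = gate_logits - logsumexp(gate_logits, axis=1, keepdims=True)
    eta = logsumexp(log_g + f, axis=1)
    return eta, f, np.exp(log_g)


def time_at_risk(curve: SurvivalCurve, threshold: float = 0.10, cap: float = 120.0) -> float:
    """First time the survival curve falls to ``threshold``.

    The curve is a right-continuous step function, so the inverse is the
    first grid time with ``S <= threshold`` (for model curves evaluated on
    a fine grid the discretization error is bounded by the grid spacing);
    returns ``cap`` when the threshold is never reached on [0, cap].
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    t = np.concatenate([[0.0], curve.times])
    s = np.concatenate([[1.0], curve.surv])
    below = np.flatnonzero(s <= threshold)
    if below.size == 0 or t[below[0]] > cap:
        return float(cap)
    return float(min(t[below[0]], cap))


@dataclass
class BimeLossParts:
    """Decomposition of one training batch's objective."""

    lcox_t0: float
    lcox_t1: float
    ipm: float
    q: float
    alpha: float
    q_t0: float
    q_t1: float
    total: float

    def identity_residual(self) -> float:
        """|total - (q*lcox0 + (1-q)*lcox1 + alpha*ipm + Q0 + Q1)|."""
        recon = (self.q * self.lcox_t0 + (1 - self.q) * self.lcox_t1
                 + self.alpha * self.ipm + self.q_t0 + self.q_t1)
        return abs(self.total - recon)

    def as_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# estimator


def _as_time_event(y):
    """Accept a structured array (event, time) a la scikit-survival, or a
    2-column array [time, event]."""
    if hasattr(y, "dtype") and y.dtype.names:
        names = y.dtype.names
        ev = [n for n in names if y[n].dtype == bool or "event" in n.lower()]
        tm = [n for n in names if n not in ev]
        return np.asarray(y[tm[0]], float), np.asarray(y[ev[0]], int)
    y = np.asarray(y, float)
    return y[:, 0], y[:, 1].astype(int)


class _ArmHead:
    """Gating + component log-hazard networks for one treatment arm."""

    def __init__(self, latent_dim, k, hidden, activation, rng):
        self.k = k
        self.gate = MLP([latent_dim, *hidden, k], activation, rng=rng)
        self.f = MLP([latent_dim, *hidden, k], activation, rng=rng, init_scale=0.05)

    @property
    def params(self):
        return self.gate.params + self.f.params

    @property
    def grads(self):
        return self.gate.grads + self.f.grads

    def zero_grad(self):
        self.gate.zero_grad()
        self.f.zero_grad()


class TarRecommenderMixin:
    """Recommendation interface shared by every two-arm survival model.

    Requires ``predict_survival_function(X, arm)`` plus ``threshold`` and
    ``cap`` attributes.
    """

    def predict_tar(self, X):
        """Per-arm times-at-risk: array (n, 2) = [TaR_NSM, TaR_MRM]."""
        out = np.zeros((len(X), 2))
        for a in (0, 1):
            for i, c in enumerate(self.predict_survival_function(X, a)):
                out[i, a] = time_at_risk(c, self.threshold, self.cap)
        return out

    def predict_ite(self, X):
        """ITE in months: TaR under MRM minus TaR under NSM."""
        tar = self.predict_tar(X)
        return tar[:, 1] - tar[:, 0]

    def predict(self, X):
        """Recommended arm: 1 (MRM) if ITE > 0 else 0 (NSM; ties -> NSM)."""
        return (self.predict_ite(X) > 0).astype(int)


class BimeRecommender(TarRecommenderMixin, BaseEstimator):
    """Balanced Cox-mixture T-learner (scikit-learn style estimator).

    Parameters
    ----------
    k : number of mixture components per arm (K=1 disables the mixture).
    alpha : weight of the latent-balancing IPM penalty (0 disables it).
    shared_encoder : one encoder for both arms (the balanced architecture);
        with ``False`` each arm gets its own encoder (a plain T-learner).
    marginal_cox : include the mixture-marginal Cox terms in the loss in
        addition to the E-step Q terms; ``False`` recovers pure
        Cox-mixture (DCM-style) training.
    encoder_hidden, latent_dim, head_hidden, activation, dropout :
        architecture of the encoder and per-arm heads.
    lr, batch_size, max_iter, patience, val_fraction : optimization.
        ``patience`` counts iterations without validation improvement.
    m_samples : Monte-Carlo assignments sampled per subject per E-step.
    e_step_every : iterations between E-steps (posterior + baselines +
        validation checkpoint).
    threshold, cap : time-at-risk definition — first month at which
        predicted survival reaches ``threshold``, capped at ``cap``.
    random_state : master seed; fitting is deterministic given it.

    Fitted attributes end in an underscore; ``predict`` returns the
    recommended arm (0 = NSM, 1 = MRM; ties go to the less invasive NSM).
    """

    def __init__(self, k=3, alpha=0.1, n_folds=5, shared_encoder=True,
                 marginal_cox=True,
                 encoder_hidden=(16,), latent_dim=8, head_hidden=(8,),
                 activation="tanh", dropout=0.2, lr=2e-3, weight_decay=1e-2,
                 batch_size=256,
                 max_iter=4000, patience=800, val_fraction=0.2, m_samples=10,
                 e_step_every=100, ipm_eps=1.0, ipm_max_points=64,
                 ipm_n_iter=30, ipm_every=4, threshold=0.10, cap=120.0,
                 standardize=True, random_state=0):
        self.k = k
        self.alpha = alpha
        self.n_folds = n_folds
        self.shared_encoder = shared_encoder
        self.marginal_cox = marginal_cox
        self.encoder_hidden = encoder_hidden
        self.latent_dim = latent_dim
        self.head_hidden = head_hidden
        self.activation = activation
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_iter = max_iter
        self.patience = patience
        self.val_fraction = val_fraction
        self.m_samples = m_samples
        self.e_step_every = e_step_every
        self.ipm_eps = ipm_eps
        self.ipm_max_points = ipm_max_points
        self.ipm_n_iter = ipm_n_iter
        self.ipm_every = ipm_every
        self.threshold = threshold
        self.cap = cap
        self.standardize = standardize
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _encoder_for(self, arm):
        return self.encoders_[0] if self.shared_encoder else self.encoders_[arm]

    def _encode(self, X, arm, train=False, rng=None):
        return self._encoder_for(arm).forward(X, train=train, rng=rng)

    def _head_forward(self, head, phi):
        gate_logits = head.gate.forward(phi)
        f = head.f.forward(phi)
        return gate_logits, f

    def _batch_loss(self, Xb, tb, eb, armb, zb, rng=None, train=True,
                    posterior_weights=None, skip_ipm=False):
        """Forward + (optionally) backward pass for one batch.

        ``zb``: sampled component assignments, shape (n, m_samples); or None
        with ``posterior_weights`` (n, k) for the deterministic expected-Q
        variant used in validation.
        Returns (BimeLossParts, phi_grads dict) with gradients accumulated
        in the networks when ``train``.
        """
        K = self.k
        parts = {}
        phis = {}
        dphis = {}
        enc_caches = {}
        for arm in (0, 1):
            m = armb == arm
            if m.sum() == 0:
                phis[arm] = None
                continue
            phi, cache = self._encoder_for(arm).forward(
                Xb[m], train=train, rng=rng, return_cache=True)
            phis[arm] = (m, phi)
            enc_caches[arm] = cache

        q = float((armb == 0).mean())

        # Cox + Q terms per arm
        lcox = {0: 0.0, 1: 0.0}
        qterm = {0: 0.0, 1: 0.0}
        head_grads_f = {}
        head_grads_gate = {}
        for arm in (0, 1):
            if phis[arm] is None:
                warnings.warn(f"arm {arm} empty in batch; its terms contribute 0")
                continue
            m, phi = phis[arm]
            head = self.heads_[arm]
            gate_logits, gate_cache = head.gate.forward(phi, return_cache=True)
            f, f_cache = head.f.forward(phi, return_cache=True)
            head._caches = (gate_cache, f_cache)
            eta, _, gates = mixture_log_hazard(gate_logits, f)
            t_a, e_a = tb[m], eb[m]
            n_a = m.sum()

            d_gate_logits = np.zeros_like(gate_logits)
            d_f = np.zeros_like(f)

            # mixture-marginal Cox term, entering the total with weight
            # q (arm 0) or 1-q (arm 1): scale its gradient at source
            cox_w = q if arm == 0 else (1.0 - q)
            if self.marginal_cox:
                nll, g_eta = cox_neg_partial_loglik(eta, t_a, e_a, return_grad=True)
                lcox[arm] = nll
                g_eta = cox_w * g_eta
                # backprop through eta = logsumexp(log g + f)
                post = softmax(np.log(np.maximum(gates, 1e-300)) + f, axis=1)
                d_f += g_eta[:, None] * post
                # d eta / d gate_logits = post - gates (softmax chain)
                d_gate_logits += g_eta[:, None] * (post - gates)
            else:
                lcox[arm] = 0.0

            # Q term: gating NLL + component-conditional Cox at assignments
            if zb is not None:
                z_a = zb[m]  # (n_a, M)
                M_s = z_a.shape[1]
                wk = np.zeros((n_a, K))
                for mm in range(M_s):
                    wk[np.arange(n_a), z_a[:, mm]] += 1.0
                wk /= M_s
            else:
                wk = posterior_weights[m]
            log_g = np.log(np.maximum(gates, 1e-300))
            gate_nll = -(wk * log_g).sum() / n_a
            comp = 0.0
            for kk in range(K):
                wcol = wk[:, kk]
                if (wcol * e_a).sum() <= 0:
                    continue
                nll_k, g_k = cox_neg_partial_loglik(f[:, kk], t_a, e_a,
                                                    weights=wcol, return_grad=True)
                comp += nll_k
                d_f[:, kk] += g_k
            qterm[arm] = gate_nll + comp
            # gating gradient: d(-sum wk log g)/d logits = (rowsum(wk) * g - wk)/n
            d_gate_logits += (wk.sum(1, keepdims=True) * gates - wk) / n_a

            head_grads_f[arm] = d_f
            head_grads_gate[arm] = d_gate_logits

        # IPM between latent clouds (subsampled for O(n^2) transport cost)
        ipm_val = 0.0
        ipm_grads = {}
        if self.alpha > 0 and not skip_ipm and phis[0] is not None and phis[1] is not None:
            sub = {}
            cap_pts = self.ipm_max_points
            for arm in (0, 1):
                phi = phis[arm][1]
                if len(phi) <= cap_pts:
                    sel = np.arange(len(phi))
                elif train and rng is not None:
                    sel = rng.choice(len(phi), cap_pts, replace=False)
                else:
                    # deterministic thinning in eval mode
                    sel = np.linspace(0, len(phi) - 1, cap_pts).astype(int)
                sub[arm] = sel
            val, g1, g0 = sinkhorn_divergence(
                phis[1][1][sub[1]], phis[0][1][sub[0]], eps=self.ipm_eps,
                n_iter=self.ipm_n_iter, return_grad=True)
            ipm_val = val
            ipm_grads = {}
            for arm, g in ((1, g1), (0, g0)):
                full = np.zeros_like(phis[arm][1])
                full[sub[arm]] = g
                ipm_grads[arm] = full

        total = (q * lcox[0] + (1 - q) * lcox[1] + self.alpha * ipm_val
                 + qterm[0] + qterm[1])
        parts = BimeLossParts(lcox_t0=lcox[0], lcox_t1=lcox[1], ipm=ipm_val,
                              q=q, alpha=self.alpha, q_t0=qterm[0],
                              q_t1=qterm[1], total=total)
        if not train:
            return parts

        # backward
        for enc in self.encoders_:
            enc.zero_grad()
        for head in self.heads_:
            head.zero_grad()
        for arm in (0, 1):
            if phis[arm] is None:
                continue
            m, phi = phis[arm]
            head = self.heads_[arm]
            d_phi = np.zeros_like(phi)
            if arm in head_grads_gate:
                gate_cache, f_cache = head._caches
                d_phi += head.gate.backward(head_grads_gate[arm], cache=gate_cache)
                d_phi += head.f.backward(head_grads_f[arm], cache=f_cache)
            if arm in ipm_grads:
                d_phi += self.alpha * ipm_grads[arm]
            self._encoder_for(arm).backward(d_phi, cache=enc_caches[arm])
        return parts

    def _iterate_minibatch(self, rng, idx0, idx1):
        n0 = max(2, int(round(self.batch_size * len(idx0) / (len(idx0) + len(idx1)))))
        n1 = max(2, self.batch_size - n0)
        b0 = rng.choice(idx0, size=min(n0, len(idx0)), replace=False)
        b1 = rng.choice(idx1, size=min(n1, len(idx1)), replace=False)
        return np.concatenate([b0, b1])

    # -- E-step helpers ----------------------------------------------------

    def _arm_forward_eval(self, X, arm):
        phi = self._encode(X, arm, train=False)
        head = self.heads_[arm]
        gate_logits = head.gate.forward(phi)
        f = head.f.forward(phi)
        eta, _, gates = mixture_log_hazard(gate_logits, f)
        return phi, gates, f, eta

    @staticmethod
    def _breslow_components(f, time, event, post):
        """Posterior-weighted Breslow baseline per component.

        Risk sets weight subject i in component k by post[i,k]*exp(f[i,k]).
        Returns list of (times, cumhaz, jumps) per component.
        """
        K = f.shape[1]
        order = np.argsort(time, kind="stable")
        t_s = time[order]
        e_s = event[order]
        out = []
        for kk in range(K):
            w = post[order, kk]
            rexp = w * np.exp(f[order, kk])
            suffix = np.cumsum(rexp[::-1])[::-1]
            uniq, first_idx = np.unique(t_s, return_index=True)
            s0 = suffix[first_idx]
            d = np.zeros(len(uniq))
            np.add.at(d, np.searchsorted(uniq, t_s), w * e_s)
            jumps = np.where(s0 > 0, d / np.maximum(s0, 1e-300), 0.0)
            out.append((uniq, np.cumsum(jumps), jumps))
        return out

    @staticmethod
    def _component_loglik(f, time, event, baselines):
        """log-likelihood of each subject under each component, using the
        component Breslow baselines (hazard jump at event times)."""
        n, K = f.shape
        ll = np.zeros((n, K))
        for kk, (bt, ch, jumps) in enumerate(baselines):
            pos = np.searchsorted(bt, time, side="right") - 1
            Lam = np.where(pos >= 0, ch[np.clip(pos, 0, None)], 0.0)
            # hazard jump exactly at t (events occur at grid times)
            at = np.searchsorted(bt, time)
            valid = (at < len(bt)) & (bt[np.clip(at, 0, len(bt) - 1)] == time)
            jump = np.where(valid, jumps[np.clip(at, 0, len(bt) - 1)], 1e-300)
            ef = np.exp(f[:, kk])
            ll[:, kk] = (event * (np.log(np.maximum(jump * ef, 1e-300)))
                         - Lam * ef)
        return ll

    def _e_step(self, X, time, event, arm_mask_pairs, rng):
        """Update posteriors, baselines and sampled assignments per arm."""
        posts, baselines, samples = {}, {}, {}
        for arm, m in arm_mask_pairs:
            if m.sum() == 0:
                continue
            phi, gates, f, eta = self._arm_forward_eval(X[m], arm)
            prev_post = self._posteriors.get(arm)
            post = prev_post if prev_post is not None and len(prev_post) == m.sum() \
                else gates
            base = self._breslow_components(f, time[m], event[m], post)
            ll = self._component_loglik(f, time[m], event[m], base)
            log_p = np.log(np.maximum(gates, 1e-300)) + ll
            post = softmax(log_p, axis=1)
            posts[arm] = post
            baselines[arm] = base
            # sample M assignments
            cum = np.cumsum(post, axis=1)
            u = rng.random((m.sum(), self.m_samples))
            samples[arm] = (u[:, :, None] > cum[:, None, :]).sum(-1)
        return posts, baselines, samples

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, treatment):
        """Fit on covariates ``X``, survival outcome ``y`` and arm labels.

        ``y`` may be a scikit-survival structured array or a 2-column
        ``[time, event]`` array; ``treatment`` is 0 (NSM) / 1 (MRM).
        """
        X = np.asarray(X, float)
        time, event = _as_time_event(y)
        arm = np.asarray(treatment, int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not set(np.unique(arm)) <= {0, 1}:
            raise ValueError("treatment must be coded 0/1")
        for a in (0, 1):
            m = arm == a
            if m.sum() == 0:
                raise ValueError(f"arm {a} has no subjects")
            if event[m].sum() == 0:
                raise ValueError(f"arm {a} has no events")
        if np.any(time <= 0):
            raise ValueError("times must be positive")

        # cross-validated ensemble: one replica per fold, each early-stopped
        # on its own held-out fold; predictions average the replicas'
        # survival functions
        if self.n_folds and self.n_folds > 1 and getattr(self, "_forced_val", None) is None:
            rng_f = np.random.default_rng(np.random.SeedSequence(self.random_state))
            folds = np.full(len(X), -1)
            for a in (0, 1):
                for e in (0, 1):
                    idx = np.flatnonzero((arm == a) & (event == e))
                    assign = np.tile(np.arange(self.n_folds),
                                     len(idx) // self.n_folds + 1)[: len(idx)]
                    folds[idx] = rng_f.permutation(assign)
            self.members_ = []
            self.training_log_ = []
            seeds = np.random.SeedSequence(self.random_state).spawn(self.n_folds)
            for f in range(self.n_folds):
                member = BimeRecommender(**self.get_params())
                member.set_params(n_folds=None,
                                  random_state=int(seeds[f].generate_state(1)[0] % (2**31)))
                member._forced_val = folds == f
                member.fit(X, y, treatment)
                for recd in member.training_log_:
                    recd = dict(recd)
                    recd["fold"] = f
                    self.training_log_.append(recd)
                self.members_.append(member)
            self.mean_ = self.members_[0].mean_
            self.scale_ = self.members_[0].scale_
            self.n_features_in_ = X.shape[1]
            self.best_iteration_ = [m.best_iteration_ for m in self.members_]
            return self
        self.members_ = None

        ss = np.random.SeedSequence(self.random_state)
        r_init, r_split, r_batch, r_estep, r_drop = (
            np.random.default_rng(c) for c in ss.spawn(5))

        if self.standardize:
            self.mean_ = X.mean(0)
            self.scale_ = np.where(X.std(0) == 0, 1.0, X.std(0))
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        self.n_features_in_ = X.shape[1]

        # validation split stratified by arm x event (or the fold the
        # ensemble driver forced on this replica)
        n = len(Xs)
        val_mask = np.zeros(n, bool)
        if getattr(self, "_forced_val", None) is not None:
            val_mask = np.asarray(self._forced_val, bool).copy()
        elif self.val_fraction > 0:
            for a in (0, 1):
                for e in (0, 1):
                    idx = np.flatnonzero((arm == a) & (event == e))
                    k = int(round(len(idx) * self.val_fraction))
                    if k > 0 and len(idx) > k:
                        val_mask[r_split.choice(idx, k, replace=False)] = True
        tr = ~val_mask
        Xtr, ttr, etr, atr = Xs[tr], time[tr], event[tr], arm[tr]
        Xva, tva, eva, ava = Xs[val_mask], time[val_mask], event[val_mask], arm[val_mask]

        latent = self.latent_dim
        n_enc = 1 if self.shared_encoder else 2
        self.encoders_ = [MLP([X.shape[1], *self.encoder_hidden, latent],
                              self.activation, dropout=self.dropout, rng=r_init)
                          for _ in range(n_enc)]
        self.heads_ = [_ArmHead(latent, self.k, self.head_hidden,
                                self.activation, r_init) for _ in range(2)]
        all_params = sum([e.params for e in self.encoders_], []) + \
            sum([h.params for h in self.heads_], [])
        all_grads = sum([e.grads for e in self.encoders_], []) + \
            sum([h.grads for h in self.heads_], [])
        opt = Adam(all_params, lr=self.lr, weight_decay=self.weight_decay)

        idx0 = np.flatnonzero(atr == 0)
        idx1 = np.flatnonzero(atr == 1)
        self._posteriors = {}
        arm_pairs = [(0, atr == 0), (1, atr == 1)]
        samples = None
        z_full = None

        self.training_log_ = []
        best_val = np.inf
        best_state = None
        best_iter = 0
        last_improve = 0

        for it in range(self.max_iter):
            if it % self.e_step_every == 0:
                posts, baselines, samples = self._e_step(Xtr, ttr, etr, arm_pairs, r_estep)
                self._posteriors = posts
                self._baselines_train = baselines
                z_full = np.zeros((len(Xtr), self.m_samples), int)
                for a, m in arm_pairs:
                    if a in samples:
                        z_full[m] = samples[a]
                # validation loss with expected (posterior) assignments
                if val_mask.sum() > 0:
                    va_pairs = [(0, ava == 0), (1, ava == 1)]
                    vposts = {}
                    pw = np.full((len(Xva), self.k), 1.0 / self.k)
                    for a, m in va_pairs:
                        if m.sum() == 0:
                            continue
                        phi, gates, f, _ = self._arm_forward_eval(Xva[m], a)
                        if a in baselines:
                            ll = self._component_loglik(f, tva[m], eva[m], baselines[a])
                            pw[m] = softmax(np.log(np.maximum(gates, 1e-300)) + ll, axis=1)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        vparts = self._batch_loss(Xva, tva, eva, ava, None,
                                                  train=False, posterior_weights=pw)
                    val_loss = vparts.total
                    if val_loss < best_val - 1e-9:
                        best_val = val_loss
                        best_state = copy.deepcopy(all_params)
                        best_iter = it
                        last_improve = it
                    elif it - last_improve >= self.patience:
                        logger.info("early stop at iteration %d (best %d)", it, best_iter)
                        break

            bidx = self._iterate_minibatch(r_batch, idx0, idx1)
            # the balance penalty is amortized: applied every ipm_every-th
            # step (its gradient is smooth relative to the Cox terms)
            skip = self.ipm_every > 1 and (it % self.ipm_every != 0)
            parts = self._batch_loss(Xtr[bidx], ttr[bidx], etr[bidx], atr[bidx],
                                     z_full[bidx], rng=r_drop, train=True,
                                     skip_ipm=skip)
            opt.step(all_grads)
            rec = parts.as_dict()
            rec["iteration"] = it
            self.training_log_.append(rec)

        if best_state is not None:
            for p, b in zip(all_params, best_state):
                p[...] = b
        self.best_iteration_ = best_iter
        self.best_val_loss_ = float(best_val) if np.isfinite(best_val) else None

        # final E-step on the full data per arm for prediction baselines
        self._posteriors = {}
        full_pairs = [(0, arm == 0), (1, arm == 1)]
        posts, baselines, _ = self._e_step(Xs, time, event, full_pairs, r_estep)
        # one refinement pass so baselines and posteriors are consistent
        self._posteriors = posts
        posts, baselines, _ = self._e_step(Xs, time, event, full_pairs, r_estep)
        self.baselines_ = baselines
        self.posteriors_ = posts
        self.event_grids_ = {a: baselines[a][0][0] for a in baselines}
        return self

    def _check_fitted(self):
        if not (hasattr(self, "heads_") or getattr(self, "members_", None)):
            raise RuntimeError("estimator is not fitted")

    def predict_survival_function(self, X, arm, times=None):
        """Predicted S(t | x, arm) as one :class:`SurvivalCurve` per row.

        ``S = sum_k g_k(phi) * exp(-Lambda_k(t) * exp(f_k(phi)))`` with the
        per-component Breslow baselines; flat beyond the last event time.
        """
        self._check_fitted()
        if arm not in (0, 1):
            raise ValueError("arm must be 0 (NSM) or 1 (MRM)")
        X = np.asarray(X, float)
        if getattr(self, "members_", None):
            if times is None:
                times = np.linspace(0.0, self.cap, 121)
            times = np.asarray(times, float)
            S = np.zeros((len(X), len(times)))
            for member in self.members_:
                for i, c in enumerate(member.predict_survival_function(X, arm, times)):
                    S[i] += c.surv
            S /= len(self.members_)
            return [SurvivalCurve(times, S[i]) for i in range(len(X))]
        Xs = (X - self.mean_) / self.scale_
        phi = self._encode(Xs, arm, train=False)
        head = self.heads_[arm]
        gate_logits = head.gate.forward(phi)
        f = head.f.forward(phi)
        _, _, gates = mixture_log_hazard(gate_logits, f)
        base = self.baselines_[arm]
        if times is None:
            times = np.unique(np.concatenate([[0.0], base[0][0], [self.cap]]))
        times = np.asarray(times, float)
        S = np.zeros((len(Xs), len(times)))
        for kk, (bt, ch, _j) in enumerate(base):
            pos = np.searchsorted(bt, times, side="right") - 1
            Lam = np.where(pos >= 0, ch[np.clip(pos, 0, None)], 0.0)
            S += gates[:, kk][:, None] * np.exp(-np.outer(np.exp(f[:, kk]), Lam))
        S = np.clip(S, 0.0, 1.0)
        S = np.minimum.accumulate(S, axis=1)  # guard monotonicity numerically
        return [SurvivalCurve(times, S[i]) for i in range(len(Xs))]

    def score(self, X, y, treatment=None):
        """Mean within-arm concordance of the marginal risk score."""
        from sksurv.metrics import concordance_index_censored

        self._check_fitted()
        if getattr(self, "members_", None):
            return float(np.mean([m.score(X, y, treatment) for m in self.members_]))
        time, event = _as_time_event(y)
        arm = np.asarray(treatment, int) if treatment is not None else None
        X = np.asarray(X, float)
        Xs = (X - self.mean_) / self.scale_
        cs = []
        for a in (0, 1):
            m = arm == a if arm is not None else np.ones(len(Xs), bool)
            if m.sum() < 3 or event[m].sum() == 0:
                continue
            _, _, _, eta = self._arm_forward_eval(Xs[m], a)
            c = concordance_index_censored(event[m].astype(bool), time[m], eta)[0]
            cs.append(c)
        return float(np.mean(cs))

    # -- persistence -------------------------------------------------------

    SCHEMA_VERSION = 1

    def _param_blobs(self):
        blobs = {"mean": self.mean_, "scale": self.scale_}
        for i, enc in enumerate(self.encoders_):
            for j, (w, b) in enumerate(zip(enc.W, enc.b)):
                blobs[f"enc{i}_W{j}"] = w
                blobs[f"enc{i}_b{j}"] = b
        for a, head in enumerate(self.heads_):
            for net_name, net in (("gate", head.gate), ("f", head.f)):
                for j, (w, b) in enumerate(zip(net.W, net.b)):
                    blobs[f"head{a}_{net_name}_W{j}"] = w
                    blobs[f"head{a}_{net_name}_b{j}"] = b
        for a, base in self.baselines_.items():
            for kk, (bt, ch, jm) in enumerate(base):
                blobs[f"base{a}_{kk}_t"] = bt
                blobs[f"base{a}_{kk}_ch"] = ch
                blobs[f"base{a}_{kk}_j"] = jm
        return blobs

    def save(self, path):
        """Serialize parameters + config to a single ``.npz`` checkpoint."""
        self._check_fitted()
        import json

        blobs = {"_schema": np.array([self.SCHEMA_VERSION]),
                 "_config": np.frombuffer(
                     json.dumps(self.get_params()).encode(), dtype=np.uint8)}
        if getattr(self, "members_", None):
            blobs["_n_members"] = np.array([len(self.members_)])
            for i, member in enumerate(self.members_):
                for key, val in member._param_blobs().items():
                    blobs[f"m{i}__{key}"] = val
                blobs[f"m{i}__seed"] = np.array([member.random_state])
        else:
            blobs.update(self._param_blobs())
        np.savez(path, **blobs)

    def _load_params(self, data, prefix=""):
        self.mean_ = data[prefix + "mean"]
        self.scale_ = data[prefix + "scale"]
        n_enc = 1 if self.shared_encoder else 2
        d_in = len(self.mean_)
        rng = np.random.default_rng(0)
        self.encoders_ = [MLP([d_in, *self.encoder_hidden, self.latent_dim],
                              self.activation, dropout=self.dropout, rng=rng)
                          for _ in range(n_enc)]
        self.heads_ = [_ArmHead(self.latent_dim, self.k, self.head_hidden,
                                self.activation, rng) for _ in range(2)]
        for i, enc in enumerate(self.encoders_):
            for j in range(len(enc.W)):
                enc.W[j] = data[f"{prefix}enc{i}_W{j}"]
                enc.b[j] = data[f"{prefix}enc{i}_b{j}"]
        for a, head in enumerate(self.heads_):
            for net_name, net in (("gate", head.gate), ("f", head.f)):
                for j in range(len(net.W)):
                    net.W[j] = data[f"{prefix}head{a}_{net_name}_W{j}"]
                    net.b[j] = data[f"{prefix}head{a}_{net_name}_b{j}"]
        self.baselines_ = {}
        for a in (0, 1):
            if f"{prefix}base{a}_0_t" in data:
                base = []
                for kk in range(self.k):
                    base.append((data[f"{prefix}base{a}_{kk}_t"],
                                 data[f"{prefix}base{a}_{kk}_ch"],
                                 data[f"{prefix}base{a}_{kk}_j"]))
                self.baselines_[a] = base
        self.n_features_in_ = d_in
        self.members_ = None

    @classmethod
    def load(cls, path):
        import json

        data = np.load(path)
        if int(data["_schema"][0]) != cls.SCHEMA_VERSION:
            raise ValueError("checkpoint schema version mismatch")
        config = json.loads(bytes(data["_config"]).decode())
        est = cls(**config)
        if "_n_members" in data:
            est.members_ = []
            for i in range(int(data["_n_members"][0])):
                member = cls(**{**config, "n_folds": None})
                member.random_state = int(data[f"m{i}__seed"][0])
                member._load_params(data, prefix=f"m{i}__")
                est.members_.append(member)
            est.mean_ = est.members_[0].mean_
            est.scale_ = est.members_[0].scale_
            est.n_features_in_ = len(est.mean_)
        else:
            est._load_params(data)
        return est
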