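"""Brain-state prediction from tPC clips with an LSTM recurrent network.

The network follows the standard gated recurrence: per layer l and step t,

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
    C~_t = tanh(W_C [h_{t-1}, x_t] + b_C)
    C_t = f_t * C_{t-1} + i_t * C~_t
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(C_t)

with a softmax readout of the final hidden state over the seven state
categories (AW/NREM/REM "only" plus the four observed transitions),
trained with softmax cross-entropy and Adam. Implemented directly in
numpy: forward, backpropagation through time, and the step-decayed
learning-rate schedule, so training is exactly reproducible from a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .glm import bh_fdr
from .io import Hypnogram

logger = logging.getLogger("sleepscape")

CATEGORIES = ("AW_only", "NREM_only", "REM_only",
              "AW_to_NREM", "NREM_to_AW", "NREM_to_REM", "REM_to_AW")


@dataclass
class LstmConfig:
    """Architecture and training schedule.

    Defaults follow the full-scale recipe (1 layer x 50 units, lr 0.01
    halved every 1000 of 8000 steps, batch 128, 500 bootstraps, 10-fold
    CV); :func:`test_profile` returns a desk-scale variant.
    """

    n_layers: int = 1
    hidden_units: int = 50
    input_dim: int = 100
    input_len: int = 5            # timesteps; 10 s at TR 2 s
    gap: int = 0                  # timesteps ahead
    lr: float = 0.01
    decay_steps: int = 1000
    decay_rate: float = 0.5
    total_steps: int = 8000
    batch_size: int = 128
    n_bootstrap: int = 500
    cv_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.input_len < 1 or self.gap < 0 or self.hidden_units < 1:
            raise ValueError("invalid LSTM configuration")
        if self.n_layers not in (1, 2, 3):
            raise ValueError("n_layers must be 1, 2 or 3")


def test_profile(**over) -> LstmConfig:
    """Reduced configuration for desk-scale runs."""
    base = dict(hidden_units=16, total_steps=250, batch_size=32,
                decay_steps=100, n_bootstrap=50, cv_folds=3)
    base.update(over)
    return LstmConfig(**base)


@dataclass
class LstmModel:
    """Gate weights/biases per layer plus the softmax readout."""

    layers: list                 # dicts with W_f, W_i, W_C, W_o, b_f..b_o
    W_s: np.ndarray              # (n_out, hidden)
    b_s: np.ndarray

    @property
    def n_out(self) -> int:
        return self.W_s.shape[0]

    def params(self) -> dict:
        out = {}
        for l, lay in enumerate(self.layers):
            for k, v in lay.items():
                out[f"l{l}_{k}"] = v
        out["W_s"] = self.W_s
        out["b_s"] = self.b_s
        return out


def init_model(cfg: LstmConfig, n_out: int,
               rng: np.random.Generator) -> LstmModel:
    cfg.validate()
    layers = []
    d = cfg.input_dim
    h = cfg.hidden_units
    for _ in range(cfg.n_layers):
        s = 1.0 / np.sqrt(h)
        lay = {}
        for g in ("f", "i", "C", "o"):
            lay[f"W_{g}"] = rng.uniform(-s, s, (h, h + d))
            lay[f"b_{g}"] = np.zeros(h)
        lay["b_f"] = np.ones(h)          # forget-gate bias init at 1
        layers.append(lay)
        d = h
    s = 1.0 / np.sqrt(h)
    return LstmModel(layers, rng.uniform(-s, s, (n_out, h)), np.zeros(n_out))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _forward_full(clips: np.ndarray, model: LstmModel):
    """Batched forward pass with caches for backpropagation.

    ``clips``: (B, L, d). Returns (probs, caches, h_last).
    """
    B, L, _ = clips.shape
    x = clips
    caches = []
    for lay in model.layers:
        h_dim = lay["W_f"].shape[0]
        h = np.zeros((B, h_dim))
        C = np.zeros((B, h_dim))
        steps = []
        hs = np.empty((B, L, h_dim))
        for t in range(L):
            cat = np.concatenate([h, x[:, t, :]], axis=1)
            f = _sigmoid(cat @ lay["W_f"].T + lay["b_f"])
            i = _sigmoid(cat @ lay["W_i"].T + lay["b_i"])
            Ct = np.tanh(cat @ lay["W_C"].T + lay["b_C"])
            C_new = f * C + i * Ct
            o = _sigmoid(cat @ lay["W_o"].T + lay["b_o"])
            h = o * np.tanh(C_new)
            steps.append({"cat": cat, "f": f, "i": i, "Ct": Ct,
                          "C_prev": C, "C": C_new, "o": o})
            C = C_new
            hs[:, t, :] = h
        caches.append({"steps": steps, "lay": lay})
        x = hs
    h_last = x[:, -1, :]
    logits = h_last @ model.W_s.T + model.b_s
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs, caches, h_last


def lstm_forward(clip: np.ndarray, model: LstmModel) -> np.ndarray:
    """Probability vector(s) over categories for one clip (L, d) or a
    batch (B, L, d); rows sum to 1."""
    clip = np.asarray(clip, float)
    single = clip.ndim == 2
    batch = clip[None] if single else clip
    probs, _, _ = _forward_full(batch, model)
    return probs[0] if single else probs


def _backward(clips, probs, onehot, caches, h_last, model: LstmModel) -> dict:
    """Gradients of mean softmax cross-entropy w.r.t. all parameters."""
    B, L, _ = clips.shape
    grads = {k: np.zeros_like(v) for k, v in model.params().items()}
    dlogits = (probs - onehot) / B
    grads["W_s"] = dlogits.T @ h_last
    grads["b_s"] = dlogits.sum(axis=0)
    h_dim = model.W_s.shape[1]
    dh_seq = np.zeros((B, L, h_dim))
    dh_seq[:, -1, :] = dlogits @ model.W_s
    for li in range(len(model.layers) - 1, -1, -1):
        lay = model.layers[li]
        steps = caches[li]["steps"]
        h_dim = lay["W_f"].shape[0]
        d_in = lay["W_f"].shape[1] - h_dim
        dh_next = np.zeros((B, h_dim))
        dC_next = np.zeros((B, h_dim))
        dx_seq = np.zeros((B, L, d_in))
        for t in range(L - 1, -1, -1):
            st = steps[t]
            dh = dh_seq[:, t, :] + dh_next
            tC = np.tanh(st["C"])
            do = dh * tC
            dC = dC_next + dh * st["o"] * (1.0 - tC ** 2)
            df = dC * st["C_prev"]
            di = dC * st["Ct"]
            dCt = dC * st["i"]
            dC_next = dC * st["f"]
            dz = {
                "f": df * st["f"] * (1 - st["f"]),
                "i": di * st["i"] * (1 - st["i"]),
                "C": dCt * (1 - st["Ct"] ** 2),
                "o": do * st["o"] * (1 - st["o"]),
            }
            dcat = np.zeros((B, h_dim + d_in))
            for g, dzg in dz.items():
                grads[f"l{li}_W_{g}"] += dzg.T @ st["cat"]
                grads[f"l{li}_b_{g}"] += dzg.sum(axis=0)
                dcat += dzg @ lay[f"W_{g}"]
            dh_next = dcat[:, :h_dim]
            dx_seq[:, t, :] = dcat[:, h_dim:]
        dh_seq = dx_seq
    return grads


class LSTMStateClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style LSTM classifier over fixed-length tPC clips.

    ``X`` has shape (n_samples, input_len, input_dim); training uses
    softmax cross-entropy with Adam and a step-decayed learning rate.
    """

    def __init__(self, n_layers: int = 1, hidden_units: int = 50,
                 lr: float = 0.01, decay_steps: int = 1000,
                 decay_rate: float = 0.5, total_steps: int = 8000,
                 batch_size: int = 128, seed: int = 0):
        self.n_layers = n_layers
        self.hidden_units = hidden_units
        self.lr = lr
        self.decay_steps = decay_steps
        self.decay_rate = decay_rate
        self.total_steps = total_steps
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMStateClassifier":
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, input_len, input_dim)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_out = self.classes_.size
        cfg = LstmConfig(n_layers=self.n_layers,
                         hidden_units=self.hidden_units,
                         input_dim=X.shape[2], input_len=X.shape[1],
                         lr=self.lr, decay_steps=self.decay_steps,
                         decay_rate=self.decay_rate,
                         total_steps=self.total_steps,
                         batch_size=self.batch_size, seed=self.seed)
        rng = np.random.default_rng(self.seed)
        model = init_model(cfg, n_out, rng)
        params = model.params()
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(vv) for k, vv in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        onehot_all = np.eye(n_out)[y_idx]
        n = X.shape[0]
        losses = []
        for step in range(cfg.total_steps):
            idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
            probs, caches, h_last = _forward_full(X[idx], model)
            oh = onehot_all[idx]
            losses.append(float(-np.log(np.clip(
                (probs * oh).sum(axis=1), 1e-12, None)).mean()))
            grads = _backward(X[idx], probs, oh, caches, h_last, model)
            lr_t = cfg.lr * cfg.decay_rate ** (step // cfg.decay_steps)
            t_adam = step + 1
            for k in params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mh = m[k] / (1 - b1 ** t_adam)
                vh = v[k] / (1 - b2 ** t_adam)
                params[k] -= lr_t * mh / (np.sqrt(vh) + eps)
        self.model_ = model
        self.loss_curve_ = np.asarray(losses)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return lstm_forward(np.asarray(X, float), self.model_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# clip extraction
# ---------------------------------------------------------------------------

def zscore_tpcs(tpcs: np.ndarray) -> np.ndarray:
    """Per-scan z-scoring of each tPC (unit variance per component)."""
    tpcs = np.asarray(tpcs, float)
    mu = tpcs.mean(axis=0)
    sd = tpcs.std(axis=0)
    return (tpcs - mu) / np.where(sd > 0, sd, 1.0)


def extract_clips(tpcs_list: Sequence[np.ndarray],
                  hyp_list: Sequence[Hypnogram], TR: float,
                  L: int = 5, gap: int = 0,
                  min_sep_s: float = 60.0,
                  max_per_category: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Build (clips, labels) over the seven categories from z-scored tPCs.

    Transition clips cover frames ``[k_trans-gap-L, k_trans-gap)``;
    "only" clips lie fully inside an epoch at least ``min_sep_s`` from any
    transition and are sampled without replacement (capped at
    ``max_per_category`` when given).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    clips, labels = [], []
    for tpcs, hyp in zip(tpcs_list, hyp_list):
        x = zscore_tpcs(tpcs)
        n_t = x.shape[0]
        trans = [(b0, f"{s0}_to_{s1}")
                 for (s0, _, b0), (s1, _, _) in zip(hyp.epochs, hyp.epochs[1:])
                 if f"{s0}_to_{s1}" in CATEGORIES]
        for t_trans, ttype in trans:
            k = int(round(t_trans / TR))
            a, b = k - gap - L, k - gap
            if a >= 0 and b <= n_t:
                clips.append(x[a:b])
                labels.append(CATEGORIES.index(ttype))
        trans_times = np.array([t for t, _ in trans]) if trans else \
            np.empty(0)
        for st, cat in (("AW", "AW_only"), ("NREM", "NREM_only"),
                        ("REM", "REM_only")):
            starts = []
            for a_s, b_s in hyp.epochs_of(st):
                k0 = int(np.ceil(a_s / TR))
                k1 = int(np.floor(b_s / TR)) - L
                for k in range(max(k0, 0), min(k1, n_t - L) + 1):
                    t0, t1 = k * TR, (k + L) * TR
                    if trans_times.size and (
                            np.min(np.abs(trans_times - t0)) < min_sep_s or
                            np.min(np.abs(trans_times - t1)) < min_sep_s):
                        continue
                    starts.append(k)
            if not starts:
                continue
            starts = np.asarray(starts)
            if max_per_category is not None and starts.size > max_per_category:
                starts = rng.choice(starts, max_per_category, replace=False)
            for k in starts:
                clips.append(x[k:k + L])
                labels.append(CATEGORIES.index(cat))
    if not clips:
        return np.empty((0, L, 0)), np.empty(0, int)
    return np.stack(clips), np.asarray(labels, int)


# ---------------------------------------------------------------------------
# bootstrap evaluation, gap curves, discriminate time
# ---------------------------------------------------------------------------

def _balanced_subsample(labels: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    cats = np.unique(labels)
    n_min = min(int((labels == c).sum()) for c in cats)
    idx = []
    for c in cats:
        pool = np.flatnonzero(labels == c)
        idx.append(rng.choice(pool, n_min, replace=False))
    return np.concatenate(idx)


def train_and_evaluate(clips: np.ndarray, labels: np.ndarray,
                       cfg: LstmConfig, n_bootstrap: Optional[int] = None,
                       with_null: bool = True,
                       keep_models: bool = False,
                       rng: Optional[np.random.Generator] = None) -> dict:
    """Bootstrap-balanced cross-validated accuracy with a shuffled-label null.

    Per bootstrap: every category subsampled to the minimum category count,
    stratified k-fold CV, per-category test accuracy (macro average) and a
    pooled confusion matrix; the null repeats the pipeline on label-shuffled
    copies. Returns accuracy arrays of shape (n_bootstrap, n_categories).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_boot = cfg.n_bootstrap if n_bootstrap is None else n_bootstrap
    cats = np.unique(labels)
    n_cat = cats.size
    n_min = min(int((labels == c).sum()) for c in cats)
    if n_min < cfg.cv_folds:
        raise ValueError(
            f"minimum category count {n_min} below {cfg.cv_folds} folds")
    acc = np.full((n_boot, n_cat), np.nan)
    null_acc = np.full((n_boot, n_cat), np.nan)
    confusion = np.zeros((n_cat, n_cat), int)
    models, model_tests = [], []

    def run_cv(X, y, seed):
        skf = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=seed)
        per_cat = np.zeros(n_cat)
        per_cat_n = np.zeros(n_cat)
        conf = np.zeros((n_cat, n_cat), int)
        last = None
        for tr_i, te_i in skf.split(X, y):
            clf = LSTMStateClassifier(
                n_layers=cfg.n_layers, hidden_units=cfg.hidden_units,
                lr=cfg.lr, decay_steps=cfg.decay_steps,
                decay_rate=cfg.decay_rate, total_steps=cfg.total_steps,
                batch_size=cfg.batch_size, seed=seed)
            clf.fit(X[tr_i], y[tr_i])
            pred = clf.predict(X[te_i])
            for ci, c in enumerate(cats):
                sel = y[te_i] == c
                per_cat[ci] += (pred[sel] == c).sum()
                per_cat_n[ci] += sel.sum()
            for yt, yp in zip(y[te_i], pred):
                conf[np.searchsorted(cats, yt), np.searchsorted(cats, yp)] += 1
            last = (clf, X[te_i], y[te_i])
        return per_cat / np.maximum(per_cat_n, 1), conf, last

    for b in range(n_boot):
        seed = int(rng.integers(2 ** 31 - 1))
        idx = _balanced_subsample(labels, rng)
        X, y = clips[idx], labels[idx]
        acc[b], conf, last = run_cv(X, y, seed)
        confusion += conf
        if keep_models and last is not None:
            models.append(last[0])
            model_tests.append((last[1], last[2]))
        if with_null:
            y_sh = rng.permutation(y)
            null_acc[b], _, _ = run_cv(X, y_sh, seed + 1)
    out = {"acc": acc, "null_acc": null_acc if with_null else None,
           "confusion": confusion, "categories": cats,
           "mean_acc": float(np.nanmean(acc)),
           "null_ci": (np.nanpercentile(null_acc, [2.5, 97.5])
                       if with_null else None)}
    if keep_models:
        out["models"] = models
        out["model_tests"] = model_tests
    return out


def gap_time_curves(tpcs_list, hyp_list, TR: float, cfg: LstmConfig,
                    gaps_s: Sequence[float], n_bootstrap: int = 50,
                    max_per_category: Optional[int] = 60,
                    rng: Optional[np.random.Generator] = None) -> dict:
    """Accuracy-vs-gap-time curves with shuffled-label null CIs."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    gaps_s = list(gaps_s)
    emp, null_hi, null_lo, per_cat, per_cat_null_hi = [], [], [], [], []
    categories = None
    for g_s in gaps_s:
        gap = int(round(g_s / TR))
        clips, labels = extract_clips(tpcs_list, hyp_list, TR,
                                      L=cfg.input_len, gap=gap,
                                      max_per_category=max_per_category,
                                      rng=rng)
        res = train_and_evaluate(clips, labels, cfg,
                                 n_bootstrap=n_bootstrap, rng=rng)
        categories = res["categories"]
        emp.append(float(np.nanmean(res["acc"])))
        per_cat.append(np.nanmean(res["acc"], axis=0))
        per_cat_null_hi.append(np.nanpercentile(res["null_acc"], 97.5, axis=0))
        boot_null = np.nanmean(res["null_acc"], axis=1)
        null_lo.append(float(np.nanpercentile(boot_null, 2.5)))
        null_hi.append(float(np.nanpercentile(boot_null, 97.5)))
    return {"gaps_s": np.asarray(gaps_s), "acc": np.asarray(emp),
            "per_category_acc": np.asarray(per_cat),
            "per_category_null_hi": np.asarray(per_cat_null_hi),
            "categories": categories,
            "null_lo": np.asarray(null_lo), "null_hi": np.asarray(null_hi)}


def discriminate_time(gaps_s: Sequence[float], acc: Sequence[float],
                      null_hi: Sequence[float]) -> float:
    """Farthest gap (s) at which accuracy beats the null 95% CI upper bound,
    requiring exceedance at every smaller gap (contiguous from gap 0)."""
    order = np.argsort(gaps_s)
    g = np.asarray(gaps_s)[order]
    exceed = np.asarray(acc)[order] > np.asarray(null_hi)[order]
    best = -1.0
    for gi, ok in zip(g, exceed):
        if not ok:
            break
        best = float(gi)
    return best


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMap:
    """Per-PC accuracy drops and their spatial reconstruction."""

    delta_acc: np.ndarray        # (n_bootstrap, p0)
    spatial_map: np.ndarray      # (v,) mean(delta_acc) @ W
    tmap: np.ndarray
    significant: np.ndarray      # FDR q<0.05 AND |Cohen's d|>0.3
    cohens_d: np.ndarray


def sensitivity_maps(models: Sequence[LSTMStateClassifier],
                     test_sets: Sequence[tuple],
                     W: np.ndarray, q: float = 0.05,
                     d_threshold: float = 0.3) -> SensitivityMap:
    """Zero each tPC in the test clips, measure the accuracy drop per
    bootstrap model, and project the mean drops through the group spatial
    weights W (p0 x v)."""
    p0 = W.shape[0]
    drops = np.zeros((len(models), p0))
    for b, (clf, (X, y)) in enumerate(zip(models, test_sets)):
        full = float((clf.predict(X) == y).mean())
        for j in range(min(p0, X.shape[2])):
            Xz = X.copy()
            Xz[:, :, j] = 0.0
            drops[b, j] = full - float((clf.predict(Xz) == y).mean())
    mean_drop = drops.mean(axis=0)
    spatial = mean_drop @ W
    per_boot = drops @ W                           # (n_boot, v)
    mu = per_boot.mean(axis=0)
    sd = per_boot.std(axis=0, ddof=1)
    n = per_boot.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(sd > 0, mu / (sd / np.sqrt(n)), 0.0)
        d = np.where(sd > 0, mu / sd, 0.0)
    p = 2 * stats.t.sf(np.abs(tmap), n - 1)
    sig = bh_fdr(p, q) & (np.abs(d) > d_threshold)
    return SensitivityMap(drops, spatial, tmap, sig, d)
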