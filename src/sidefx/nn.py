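"""Multilayer sigmoid network trained by online backpropagation.

The classifier is a fully connected net with one hidden layer of logistic
units. Outputs are sigmoid thresholdings of the scalar product of weight and
input vectors; training minimises the squared error E = 1/2 sum (y - s)^2 by
per-probe (online) gradient descent with the update rules

    dw_ij = alpha * eps_i * s_j * s_i (1 - s_i)
    dw_jk = alpha * sum_i eps_i * s_k * s_i (1 - s_i) * w_ij * s_j (1 - s_j)

with eps_i = y_i - s_i. These are exactly the squared-error gradients for
logistic activations (the decisive correctness check is a finite-difference
comparison in the test-suite). Bias terms are realised as a clamped constant
unit (s = 1) in the input and hidden layers, so the update rules apply to
them unchanged.

Model selection uses seeded random restarts plus a random-walk strategy
(Gaussian perturbations of the best weights with decaying scale) to
distinguish local from global minima, and stratified k-fold cross-validation
(k = 10 by default) for honest false-negative/false-positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "NNConfig",
    "NNModel",
    "CVReport",
    "train",
    "cross_validate",
    "fn_constrained_fp",
    "prepare_inputs",
]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class NNConfig:
    n_hidden: int | None = None       # default: ceil(sqrt(n_inputs))
    learning_rate: float = 1.0
    max_epochs: int = 200
    tol: float = 1e-6                 # convergence tolerance on the error
    n_restarts: int = 5
    walk_scale: float = 1.0           # initial random-walk perturbation scale
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_hidden is not None and self.n_hidden < 1:
            raise ValueError("need at least one hidden unit (nonlinear model)")


@dataclass
class NNModel:
    w_hidden: np.ndarray   # (n_hidden, n_inputs + 1), last column = bias unit
    w_out: np.ndarray      # (n_outputs, n_hidden + 1)
    error_trace: list = field(default_factory=list)
    restart_errors: list = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1] - 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Activations of the output layer for a single probe or a batch.

        Inputs are expected scaled to [0, 1]; all activations lie in (0, 1).
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {X.shape[1]}")
        Xb = np.hstack([X, np.ones((X.shape[0], 1))])
        s_j = _sigmoid(Xb @ self.w_hidden.T)
        s_jb = np.hstack([s_j, np.ones((s_j.shape[0], 1))])
        s_i = _sigmoid(s_jb @ self.w_out.T)
        return s_i[0] if single else s_i

    def hidden(self, x: np.ndarray) -> np.ndarray:
        Xb = np.append(np.asarray(x, dtype=float), 1.0)
        return _sigmoid(self.w_hidden @ Xb)


def probe_updates(
    model: NNModel, x: np.ndarray, y: np.ndarray, alpha: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """The printed per-probe weight improvements (dw_out, dw_hidden).

    Exposed separately so the gradient-descent property (dw = -alpha dE/dw for
    the squared error of this probe) can be verified directly.
    """
    xb = np.append(np.asarray(x, dtype=float), 1.0)
    s_j = _sigmoid(model.w_hidden @ xb)
    s_jb = np.append(s_j, 1.0)
    s_i = _sigmoid(model.w_out @ s_jb)
    eps = np.asarray(y, dtype=float) - s_i
    gi = eps * s_i * (1 - s_i)                      # per-output factor
    dw_out = alpha * np.outer(gi, s_jb)
    back = (model.w_out[:, :-1].T @ gi) * s_j * (1 - s_j)
    dw_hidden = alpha * np.outer(back, xb)
    return dw_out, dw_hidden


def _sse(model: NNModel, X: np.ndarray, Y: np.ndarray) -> float:
    out = model.forward(X)
    return float(0.5 * np.sum((Y - out) ** 2))


def train(X, y, config: NNConfig | None = None) -> NNModel:
    """Fit the network by online backpropagation with random-walk restarts.

    ``X``: (n, p) inputs scaled to [0, 1]; ``y``: binary targets, shape (n,)
    or (n, k) for simultaneous discrimination of several outputs. The first
    restart initialises weights uniformly in [-0.5, 0.5]; subsequent restarts
    perturb the best weights so far with Gaussian noise of decaying scale.
    Divergent restarts (non-finite error) are abandoned. Returns the model
    with the lowest final training error; its mean-per-probe error trace is
    recorded.
    """
    config = config or NNConfig()
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(y, dtype=float).T).T if np.ndim(y) == 1 else np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(Y):
        raise ValueError("X must be (n, p) aligned with y")
    n, p = X.shape
    n_out = Y.shape[1]
    n_hidden = config.n_hidden or max(1, int(np.ceil(np.sqrt(p))))
    ss = np.random.SeedSequence([config.seed, 707])
    rngs = [np.random.default_rng(s) for s in ss.spawn(config.n_restarts)]
    Xb = np.hstack([X, np.ones((n, 1))])

    best: NNModel | None = None
    best_err = np.inf
    restart_errors = []
    for r, rng in enumerate(rngs):
        if best is None or r == 0:
            w_h = rng.uniform(-0.5, 0.5, (n_hidden, p + 1))
            w_o = rng.uniform(-0.5, 0.5, (n_out, n_hidden + 1))
        else:  # random walk around the current best
            scale = config.walk_scale * 0.5 ** (r - 1)
            w_h = best.w_hidden + rng.normal(0, scale, best.w_hidden.shape)
            w_o = best.w_out + rng.normal(0, scale, best.w_out.shape)
        model = NNModel(w_h.copy(), w_o.copy())
        trace = []
        prev = np.inf
        diverged = False
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            for v in order:
                xb = Xb[v]
                s_j = _sigmoid(model.w_hidden @ xb)
                s_jb = np.append(s_j, 1.0)
                s_i = _sigmoid(model.w_out @ s_jb)
                gi = (Y[v] - s_i) * s_i * (1 - s_i)
                back = (model.w_out[:, :-1].T @ gi) * s_j * (1 - s_j)
                model.w_out += config.learning_rate * np.outer(gi, s_jb)
                model.w_hidden += config.learning_rate * np.outer(back, xb)
            err = _sse(model, X, Y) / n
            if not np.isfinite(err):
                diverged = True
                break
            trace.append(err)
            if abs(prev - err) < config.tol:
                break
            prev = err
        if diverged:
            restart_errors.append(np.nan)
            continue
        final = trace[-1] if trace else np.inf
        restart_errors.append(final)
        if final < best_err:
            best_err = final
            model.error_trace = trace
            best = model
    if best is None:
        raise RuntimeError("all restarts diverged")
    best.restart_errors = restart_errors
    return best


@dataclass
class CVReport:
    fold_table: pd.DataFrame     # per-fold confusion counts and rates
    pooled_fn_rate: float
    pooled_fp_rate: float
    pooled_error_rate: float
    scores: np.ndarray           # pooled out-of-fold scores
    labels: np.ndarray
    threshold: float = 0.5


def cross_validate(X, y, config: NNConfig | None = None) -> CVReport:
    """Stratified k-fold cross-validation of the classifier.

    Partitions the data into k near-equal parts (sizes differ by at most 1,
    stratified on the label); each part is tested exactly once by a model
    trained on the remaining k-1 parts. Rates at the 0.5 output threshold:
    FN rate = FN / (FN + TP) among positives, FP rate = FP / (FP + TN) among
    negatives.
    """
    config = config or NNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < config.k_folds:
        raise ValueError("need n >= k_folds")
    # stratify when every class can appear in every fold; otherwise (e.g.
    # leave-one-out) fall back to a plain shuffled partition
    min_class = int(np.unique(y, return_counts=True)[1].min())
    splitter = StratifiedKFold if min_class >= config.k_folds else KFold
    skf = splitter(n_splits=config.k_folds, shuffle=True, random_state=config.seed % (2**32))
    scores = np.empty(len(y))
    fold_rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        sub_cfg = NNConfig(**{**config.__dict__, "seed": config.seed + 1000 + fold})
        model = train(X[tr], y[tr], sub_cfg)
        s = model.forward(X[te])[:, 0]
        scores[te] = s
        pred = s >= 0.5
        yt = y[te].astype(bool)
        tp = int((pred & yt).sum()); fn = int((~pred & yt).sum())
        fp = int((pred & ~yt).sum()); tn = int((~pred & ~yt).sum())
        fold_rows.append(
            dict(fold=fold, n=len(te), tp=tp, fn=fn, fp=fp, tn=tn,
                 fn_rate=fn / max(tp + fn, 1), fp_rate=fp / max(fp + tn, 1))
        )
    tab = pd.DataFrame(fold_rows)
    pos = y.astype(bool)
    pred = scores >= 0.5
    fn_rate = float((~pred & pos).sum() / max(pos.sum(), 1))
    fp_rate = float((pred & ~pos).sum() / max((~pos).sum(), 1))
    err = float((pred != pos).mean())
    return CVReport(tab, fn_rate, fp_rate, err, scores, y.astype(int))


def fn_constrained_fp(
    scores, labels, max_fn_rate: float = 0.15
) -> tuple[float, float, float]:
    """False-positive rate when the decision threshold is forced to keep the
    false-negative rate below ``max_fn_rate``.

    Chooses the largest threshold on the (pooled, out-of-fold) scores whose FN
    rate stays strictly below the constraint, then reports (threshold,
    fn_rate, fp_rate). On uninformative scores this necessarily drives the FP
    rate towards 1 - max_fn_rate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos = np.sort(s[y])
    if len(pos) == 0:
        raise ValueError("need positive cases")
    # threshold just below the max_fn quantile of positive scores
    k = int(np.floor(max_fn_rate * len(pos)))
    k = min(k, len(pos) - 1)
    thr = pos[k] - 1e-12 if k > 0 else pos[0] - 1e-12
    fn = float((s[y] < thr).mean())
    fp = float((s[~y] >= thr).mean())
    return float(thr), fn, fp


def prepare_inputs(
    vectors: pd.DataFrame,
    gene_weights: pd.Series | None = None,
    mode: str = "normalized",
    screen_table: pd.DataFrame | None = None,
    snps_per_gene: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the network's input matrix from gene vectors.

    ``mode="normalized"``: each gene's vector code is scaled to [0, 1] by
    3^m - 1 and multiplied by the gene's screening weight (default weight 1).
    Invalid vectors enter as the uninformative midpoint 0.5 (times weight).
    ``mode="indicators"``: one input per screened gene x direction from
    ``screen_table`` — the 0/1 indicator of carrying a flagged pattern,
    times the gene weight.
    """
    if mode == "normalized":
        if snps_per_gene is None:
            raise ValueError("normalized mode needs snps_per_gene (m per gene)")
        cols = {}
        for gene in vectors.columns:
            m = int(snps_per_gene[gene])
            w = 1.0 if gene_weights is None else float(gene_weights.get(gene, 0.0))
            v = vectors[gene].to_numpy(dtype=float) / (3.0**m - 1.0)
            v = np.where(np.isnan(v), 0.5, v)
            cols[gene] = w * v
        return pd.DataFrame(cols, index=vectors.index)
    if mode == "indicators":
        if screen_table is None:
            raise ValueError("indicator mode needs the screening table")
        flagged = screen_table[screen_table["patterns"].map(len) > 0]
        cols = {}
        for row in flagged.itertuples(index=False):
            gene = row.gene_id
            w = 1.0 if gene_weights is None else float(gene_weights.get(gene, 0.0))
            codes = vectors[gene].to_numpy(dtype=float)
            ind = np.isin(codes, np.asarray(row.patterns, dtype=float)).astype(float)
            cols[f"{gene}:{row.direction}"] = w * ind
        if not cols:
            raise ValueError("no flagged patterns to encode")
        return pd.DataFrame(cols, index=vectors.index)
    raise ValueError("mode must be 'normalized' or 'indicators'")
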