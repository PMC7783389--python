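"""Linear-chain conditional random field, implemented natively.

The model assigns a label sequence y for a token sequence with features x the
score

    score(x, y) = sum_t [ state(x_t, y_t) + trans(y_{t-1}, y_t) ]

(no transition term at t = 0), and probability
``exp(score - log Z)`` where ``log Z`` is computed by the forward recursion in
log space.  State potentials are sums of weights of active feature atoms —
``name=value`` string pairs hashed to integer ids at fit time; transition
potentials are plain label-pair weights.  Training maximizes

    sum_i [ score(x_i, y_i) - log Z(x_i) ] - c2 ||w||^2 - c1 ||w||_1

with L-BFGS, using forward-backward marginals for the expected feature counts
and a subgradient for the L1 term.  All arithmetic is in log space; the
forward/backward passes are vectorized across sequences (padded to the longest
sequence with masking) so training scales to thousands of abstracts on one
core.

Feature atoms unseen at fit time are ignored at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from sklearn.model_selection import KFold

__all__ = [
    "CRFConfig",
    "CRFModel",
    "featmap_atoms",
    "sequence_score",
    "log_partition",
    "log_likelihood_and_gradient",
    "viterbi_decode",
    "fit",
    "tune_hyperparameters",
]


@dataclass(frozen=True)
class CRFConfig:
    """Training hyperparameters.

    c1/c2 are the L1/L2 regularization weights; tolerance is the relative
    objective-decrease threshold handed to the optimizer.
    """

    c1: float = 0.1
    c2: float = 0.1
    max_iterations: int = 100
    tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class CRFModel:
    """A fitted (or hand-constructed) linear-chain CRF.

    ``state_weights`` has shape (n_atoms, n_labels); ``transition_weights``
    has shape (n_labels, n_labels) indexed (from, to).  The label alphabet and
    feature index are frozen after fit.
    """

    label_alphabet: tuple[str, ...]
    feature_index: dict[str, int]
    state_weights: np.ndarray
    transition_weights: np.ndarray
    config: CRFConfig = field(default_factory=CRFConfig)
    converged: bool = True

    def __post_init__(self) -> None:
        self.state_weights = np.asarray(self.state_weights, dtype=np.float64)
        self.transition_weights = np.asarray(self.transition_weights, dtype=np.float64)
        L = len(self.label_alphabet)
        if self.state_weights.shape != (len(self.feature_index), L):
            raise ValueError("state_weights shape mismatch")
        if self.transition_weights.shape != (L, L):
            raise ValueError("transition_weights shape mismatch")
        if not (np.isfinite(self.state_weights).all() and np.isfinite(self.transition_weights).all()):
            raise ValueError("weights must be finite")

    def label_id(self, label: str) -> int:
        try:
            return self.label_alphabet.index(label)
        except ValueError:
            raise ValueError(f"unknown label {label!r}") from None


def featmap_atoms(fm: dict) -> list[str]:
    """Flatten a token feature dictionary into ``name=value`` atom strings."""
    return [f"{k}={v}" for k, v in fm.items()]


def _atom_ids(model_index: dict[str, int], feats: list[dict]) -> list[np.ndarray]:
    out = []
    for fm in feats:
        ids = [model_index[a] for a in featmap_atoms(fm) if a in model_index]
        out.append(np.asarray(ids, dtype=np.int64))
    return out


def _state_scores(model: CRFModel, feats: list[dict]) -> np.ndarray:
    """(T, L) matrix of state potentials for one sequence."""
    L = len(model.label_alphabet)
    S = np.zeros((len(feats), L))
    for t, ids in enumerate(_atom_ids(model.feature_index, feats)):
        if ids.size:
            S[t] = model.state_weights[ids].sum(axis=0)
    return S


def sequence_score(model: CRFModel, feats: list[dict], labels: list[str]) -> float:
    """Unnormalized log score of one labeling of one sequence."""
    if len(feats) != len(labels):
        raise ValueError("feats/labels length mismatch")
    y = [model.label_id(lab) for lab in labels]
    S = _state_scores(model, feats)
    score = float(S[np.arange(len(y)), y].sum())
    for a, b in zip(y, y[1:]):
        score += float(model.transition_weights[a, b])
    return score


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    mx = a.max(axis=axis, keepdims=True)
    return (mx + np.log(np.exp(a - mx).sum(axis=axis, keepdims=True))).squeeze(axis)


def log_partition(model: CRFModel, feats: list[dict]) -> float:
    """log sum over all label sequences of exp(sequence_score), by the forward
    recursion with log-sum-exp stabilization."""
    if not feats:
        raise ValueError("empty sequence")
    S = _state_scores(model, feats)
    Wt = model.transition_weights
    alpha = S[0]
    for t in range(1, len(feats)):
        alpha = _logsumexp(alpha[:, None] + Wt, axis=0) + S[t]
    return float(_logsumexp(alpha, axis=0))


def viterbi_decode(model: CRFModel, feats: list[dict]) -> list[str]:
    """A maximum-score labeling.

    Ties are broken toward the earliest label in alphabet order at the latest
    differing position (argmax takes the first index, and backtracking then
    picks the smallest predecessor), so decoding is fully deterministic.
    """
    if not feats:
        raise ValueError("empty sequence")
    S = _state_scores(model, feats)
    Wt = model.transition_weights
    T, L = S.shape
    bp = np.zeros((T, L), dtype=np.int64)
    delta = S[0]
    for t in range(1, T):
        a = delta[:, None] + Wt
        bp[t] = np.argmax(a, axis=0)
        delta = a[bp[t], np.arange(L)] + S[t]
    path = [int(np.argmax(delta))]
    for t in range(T - 1, 0, -1):
        path.append(int(bp[t, path[-1]]))
    path.reverse()
    return [model.label_alphabet[i] for i in path]


# ---------------------------------------------------------------------------
# Packed dataset + batched objective used by training.


class _Packed:
    """Sequences packed for vectorized forward-backward.

    Tokens are stored sequence-major; (seq_idx, pos_idx) scatter them into a
    (n_seq, T_max, L) padded tensor.
    """

    def __init__(self, atom_ids: list[list[np.ndarray]], labels: list[np.ndarray], n_atoms: int, L: int):
        self.L = L
        self.n_atoms = n_atoms
        self.lengths = np.array([len(seq) for seq in atom_ids], dtype=np.int64)
        if (self.lengths == 0).any():
            raise ValueError("empty sequence in training data")
        self.n_seq = len(atom_ids)
        self.T_max = int(self.lengths.max())
        self.n_tok = int(self.lengths.sum())
        self.seq_idx = np.repeat(np.arange(self.n_seq), self.lengths)
        self.pos_idx = np.concatenate([np.arange(n) for n in self.lengths])
        self.y = np.concatenate(labels)
        # sparse indicator matrix token x atom
        indptr = np.zeros(self.n_tok + 1, dtype=np.int64)
        cols = []
        t = 0
        for seq in atom_ids:
            for ids in seq:
                cols.append(ids)
                t += 1
                indptr[t] = indptr[t - 1] + len(ids)
        data = np.ones(int(indptr[-1]), dtype=np.float64)
        self.X = sp.csr_matrix(
            (data, np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64), indptr),
            shape=(self.n_tok, n_atoms),
        )
        # observed transition pairs (exclude sequence boundaries)
        starts = np.concatenate([[0], np.cumsum(self.lengths)])[:-1]
        keep = np.ones(self.n_tok, dtype=bool)
        keep[starts] = False
        self.trans_to = self.y[keep]
        self.trans_from = self.y[np.flatnonzero(keep) - 1]
        self.obs_trans = np.zeros((L, L))
        np.add.at(self.obs_trans, (self.trans_from, self.trans_to), 1.0)
        # validity masks for padded positions / pairs
        pos = np.arange(self.T_max)
        self.tok_mask = pos[None, :] < self.lengths[:, None]
        self.pair_mask = pos[None, : self.T_max - 1] < (self.lengths - 1)[:, None]

    def objective(self, w: np.ndarray, c1: float, c2: float) -> tuple[float, np.ndarray]:
        """Penalized log-likelihood (to maximize) and its (sub)gradient."""
        L, nA = self.L, self.n_atoms
        Ws = w[: nA * L].reshape(nA, L)
        Wt = w[nA * L :].reshape(L, L)
        S_tok = self.X @ Ws
        S = np.zeros((self.n_seq, self.T_max, L))
        S[self.seq_idx, self.pos_idx] = S_tok

        alpha = np.empty_like(S)
        alpha[:, 0] = S[:, 0]
        for t in range(1, self.T_max):
            prev = alpha[:, t - 1]
            a = prev[:, :, None] + Wt[None, :, :]
            mx = a.max(axis=1)
            cur = mx + np.log(np.exp(a - mx[:, None, :]).sum(axis=1)) + S[:, t]
            act = (t < self.lengths)[:, None]
            alpha[:, t] = np.where(act, cur, prev)
        last = alpha[:, -1]
        mx = last.max(axis=1)
        logZ = mx + np.log(np.exp(last - mx[:, None]).sum(axis=1))

        beta = np.zeros_like(S)
        for t in range(self.T_max - 2, -1, -1):
            nxt = S[:, t + 1] + beta[:, t + 1]
            a = Wt[None, :, :] + nxt[:, None, :]
            mx2 = a.max(axis=2)
            val = mx2 + np.log(np.exp(a - mx2[:, :, None]).sum(axis=2))
            act = (t <= self.lengths - 2)[:, None]
            beta[:, t] = np.where(act, val, beta[:, t])

        # log-likelihood of observed labelings
        ll = float(S_tok[np.arange(self.n_tok), self.y].sum())
        ll += float(Wt[self.trans_from, self.trans_to].sum())
        ll -= float(logZ.sum())

        # state marginals at real token positions
        logM = alpha + beta - logZ[:, None, None]
        P_tok = np.exp(logM[self.seq_idx, self.pos_idx])
        D = -P_tok
        D[np.arange(self.n_tok), self.y] += 1.0
        grad_state = np.asarray(self.X.T @ D)

        # pairwise marginals -> expected transition counts
        if self.T_max > 1:
            A = (
                alpha[:, :-1, :, None]
                + Wt[None, None, :, :]
                + (S + beta)[:, 1:, None, :]
                - logZ[:, None, None, None]
            )
            A = np.where(self.pair_mask[:, :, None, None], A, -np.inf)
            E_trans = np.exp(A).sum(axis=(0, 1))
        else:
            E_trans = np.zeros((L, L))
        grad_trans = self.obs_trans - E_trans

        f = ll - c2 * float(w @ w) - c1 * float(np.abs(w).sum())
        g = np.concatenate([grad_state.ravel(), grad_trans.ravel()])
        g -= 2.0 * c2 * w + c1 * np.sign(w)
        return f, g


def _index_data(
    data: list[tuple[list[dict], list[str]]],
    feature_index: dict[str, int],
    alphabet: tuple[str, ...],
) -> _Packed:
    lab_id = {lab: i for i, lab in enumerate(alphabet)}
    atom_ids = []
    labels = []
    for feats, labs in data:
        if len(feats) != len(labs):
            raise ValueError("feats/labels length mismatch")
        atom_ids.append(
            [
                np.asarray(
                    [feature_index[a] for a in featmap_atoms(fm) if a in feature_index],
                    dtype=np.int64,
                )
                for fm in feats
            ]
        )
        labels.append(np.asarray([lab_id[l] for l in labs], dtype=np.int64))
    return _Packed(atom_ids, labels, len(feature_index), len(alphabet))


def log_likelihood_and_gradient(
    model: CRFModel, data: list[tuple[list[dict], list[str]]]
) -> tuple[float, np.ndarray]:
    """Regularized log-likelihood of the data under the model's current
    weights, with its (sub)gradient over [state_weights, transition_weights]."""
    if not data:
        raise ValueError("empty data")
    packed = _index_data(data, model.feature_index, model.label_alphabet)
    w = np.concatenate([model.state_weights.ravel(), model.transition_weights.ravel()])
    return packed.objective(w, model.config.c1, model.config.c2)


def fit(
    train: list[tuple[list[dict], list[str]]],
    config: CRFConfig | None = None,
    callback=None,
    alphabet: tuple[str, ...] | None = None,
) -> CRFModel:
    """Train a CRF by L-BFGS on the regularized likelihood.

    The label alphabet is the sorted set of labels observed in training unless
    a fixed alphabet is supplied; the feature index maps every atom observed
    in training to a column.  Training is deterministic given the data
    (initialization is zero; the optimizer is deterministic), so two fits on
    identical data yield identical weights.
    """
    if not train:
        raise ValueError("empty training set")
    config = config or CRFConfig()
    observed = {lab for _, labs in train for lab in labs}
    if alphabet is None:
        alphabet = tuple(sorted(observed))
    elif not observed <= set(alphabet):
        raise ValueError(f"training labels {observed - set(alphabet)} outside alphabet")
    atoms = sorted({a for feats, _ in train for fm in feats for a in featmap_atoms(fm)})
    feature_index = {a: i for i, a in enumerate(atoms)}
    packed = _index_data(train, feature_index, alphabet)
    L = len(alphabet)

    def neg(w):
        f, g = packed.objective(w, config.c1, config.c2)
        return -f, -g

    w0 = np.zeros(len(atoms) * L + L * L)
    res = scipy.optimize.minimize(
        neg,
        w0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_iterations,
            "ftol": config.tolerance,
            "gtol": 1e-12,
            "maxcor": 10,
        },
    )
    converged = bool(res.success) or "REL_REDUCTION" in str(res.message)
    if not converged:
        warnings.warn(f"CRF training did not converge: {res.message}", RuntimeWarning)
    w = res.x
    return CRFModel(
        label_alphabet=alphabet,
        feature_index=feature_index,
        state_weights=w[: len(atoms) * L].reshape(len(atoms), L).copy(),
        transition_weights=w[len(atoms) * L :].reshape(L, L).copy(),
        config=config,
        converged=converged,
    )


def _macro_f1(gold: list[list[str]], pred: list[list[str]]) -> float:
    """Unweighted mean one-vs-rest F1 over all labels seen in gold or pred."""
    labels = sorted({l for seq in gold for l in seq} | {l for seq in pred for l in seq})
    f1s = []
    for lab in labels:
        tp = fp = fn = 0
        for g_seq, p_seq in zip(gold, pred):
            for g, p in zip(g_seq, p_seq):
                if p == lab and g == lab:
                    tp += 1
                elif p == lab:
                    fp += 1
                elif g == lab:
                    fn += 1
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return float(np.mean(f1s)) if f1s else 0.0


def tune_hyperparameters(
    train: list[tuple[list[dict], list[str]]],
    grid: list[CRFConfig],
    k: int = 5,
    seed: int = 0,
) -> CRFConfig:
    """Pick the grid config maximizing mean k-fold cross-validated macro-F1.

    Ties break toward the smallest (c1, c2) lexicographically.  Duplicate
    configs in the grid are evaluated once.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(train) < k:
        raise ValueError("fewer sequences than folds")
    uniq: list[CRFConfig] = []
    for cfg in grid:
        if cfg not in uniq:
            uniq.append(cfg)
    splits = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(train))
    best: tuple[float, tuple[float, float], CRFConfig] | None = None
    for cfg in uniq:
        scores = []
        for tr_idx, te_idx in splits:
            model = fit([train[i] for i in tr_idx], cfg)
            gold = [train[i][1] for i in te_idx]
            pred = [viterbi_decode(model, train[i][0]) for i in te_idx]
            scores.append(_macro_f1(gold, pred))
        key = (-float(np.mean(scores)), (cfg.c1, cfg.c2))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], cfg)
    return best[2]
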