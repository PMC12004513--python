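"""Directed message-passing neural network classifier.

Messages live on *directed* bonds.  An edge u->v is initialized from the
source-atom and bond features; at each of ``depth`` update rounds it
aggregates (sums) the messages of edges incoming to u, excluding its own
reverse edge v->u, passes them through a shared linear layer and a ReLU,
with a skip connection to the initial edge state.  Atom states then
aggregate incident edge messages, the molecule embedding is the mean over
atom states (optionally concatenated with a normalized global-descriptor
vector), and a feed-forward readout with a sigmoid output yields P(PBT).

Implemented directly on NumPy with hand-written backpropagation (binary
cross-entropy loss, Adam, linear warmup + exponential learning-rate decay);
training is deterministic per seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .chemprep import MoleculeRecord
from .featurize import (
    ATOM_FDIM,
    BOND_FDIM,
    DescriptorCalculator,
    MolGraph,
    Normalizer,
    fit_normalizer,
    mol_to_graph,
)
from . import evalkit
from .splitkit import SplitResult, carve_validation


@dataclass
class ModelConfig:
    """Hyperparameters; the defaults follow the reference architecture's
    standard setting (ReLU, batch 50, depth 3, 30 epochs, FFN 300x2)."""

    hidden_size: int = 300
    depth: int = 3
    epochs: int = 30
    batch_size: int = 50
    ffn_hidden_size: int = 300
    ffn_num_layers: int = 2
    use_global_descriptors: bool = True
    descriptor_names: Optional[list[str]] = None  # None -> toolkit default 200
    threshold: float = 0.5
    seed: int = 0
    init_lr: float = 1e-4
    max_lr: float = 1e-3
    final_lr: float = 1e-4
    warmup_epochs: float = 2.0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# batching

@dataclass
class _Batch:
    atom_features: np.ndarray
    bond_features: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    atom_mol: np.ndarray   # molecule index of each atom
    n_mols: int
    atom_counts: np.ndarray


def _batch_graphs(graphs: Sequence[MolGraph]) -> _Batch:
    atom_feats, bond_feats, srcs, dsts, revs, atom_mol = [], [], [], [], [], []
    a_off = e_off = 0
    counts = []
    for i, g in enumerate(graphs):
        atom_feats.append(g.atom_features)
        bond_feats.append(g.bond_features)
        srcs.append(g.src + a_off)
        dsts.append(g.dst + a_off)
        revs.append(g.rev + e_off)
        atom_mol.append(np.full(g.n_atoms, i, dtype=np.intp))
        counts.append(g.n_atoms)
        a_off += g.n_atoms
        e_off += g.n_edges
    return _Batch(
        atom_features=np.concatenate(atom_feats),
        bond_features=np.concatenate(bond_feats) if e_off else np.zeros((0, BOND_FDIM)),
        src=np.concatenate(srcs) if e_off else np.zeros(0, dtype=np.intp),
        dst=np.concatenate(dsts) if e_off else np.zeros(0, dtype=np.intp),
        rev=np.concatenate(revs) if e_off else np.zeros(0, dtype=np.intp),
        atom_mol=np.concatenate(atom_mol),
        n_mols=len(graphs),
        atom_counts=np.asarray(counts, dtype=np.float64),
    )


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _segment_sum(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, index, values)
    return out


class _Params(dict):
    """Named parameter arrays with elementwise arithmetic helpers."""


def _init_params(cfg: ModelConfig, d_desc: int, rng: np.random.Generator) -> _Params:
    def xavier(fan_in, fan_out):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, scale, size=(fan_in, fan_out))

    H = cfg.hidden_size
    p = _Params()
    p["Wi"] = xavier(ATOM_FDIM + BOND_FDIM, H)
    p["bi"] = np.zeros(H)
    p["Wh"] = xavier(H, H)
    p["Wo"] = xavier(ATOM_FDIM + H, H)
    p["bo"] = np.zeros(H)
    z_dim = H + (d_desc if cfg.use_global_descriptors else 0)
    dims = [z_dim] + [cfg.ffn_hidden_size] * (cfg.ffn_num_layers - 1) + [1]
    for i in range(len(dims) - 1):
        p[f"Wf{i}"] = xavier(dims[i], dims[i + 1])
        p[f"bf{i}"] = np.zeros(dims[i + 1])
    return p


def _forward(
    params: _Params, cfg: ModelConfig, batch: _Batch, desc: Optional[np.ndarray]
) -> tuple[np.ndarray, dict]:
    """Batched forward pass; returns logits and a cache for backprop."""
    A, E = batch.atom_features, batch.bond_features
    src, dst, rev = batch.src, batch.dst, batch.rev
    n_atoms = A.shape[0]

    Ecat = np.concatenate([A[src], E], axis=1)
    Z0 = Ecat @ params["Wi"] + params["bi"]
    H0 = _relu(Z0)
    H = H0
    Ms, Hs = [], [H0]
    for _ in range(cfg.depth):
        S = _segment_sum(H, dst, n_atoms)
        M = S[src] - H[rev]
        H = _relu(H0 + M @ params["Wh"])
        Ms.append(M)
        Hs.append(H)
    S_final = _segment_sum(H, dst, n_atoms)
    Acat = np.concatenate([A, S_final], axis=1)
    Aout = _relu(Acat @ params["Wo"] + params["bo"])
    mol = _segment_sum(Aout, batch.atom_mol, batch.n_mols) / batch.atom_counts[:, None]
    if cfg.use_global_descriptors:
        if desc is None:
            raise ValueError("model expects global descriptors")
        z = np.concatenate([mol, desc], axis=1)
    else:
        z = mol
    acts = [z]
    n_ffn = cfg.ffn_num_layers
    h = z
    for i in range(n_ffn - 1):
        h = _relu(h @ params[f"Wf{i}"] + params[f"bf{i}"])
        acts.append(h)
    logits = (h @ params[f"Wf{n_ffn - 1}"] + params[f"bf{n_ffn - 1}"]).ravel()
    cache = dict(Ecat=Ecat, H0=H0, Ms=Ms, Hs=Hs, Acat=Acat, Aout=Aout,
                 acts=acts, batch=batch)
    return logits, cache


def _backward(
    params: _Params, cfg: ModelConfig, cache: dict, dlogits: np.ndarray
) -> _Params:
    batch: _Batch = cache["batch"]
    A = batch.atom_features
    src, dst, rev = batch.src, batch.dst, batch.rev
    n_atoms = A.shape[0]
    H = cfg.hidden_size
    grads = _Params({k: np.zeros_like(v) for k, v in params.items()})

    n_ffn = cfg.ffn_num_layers
    dh = dlogits[:, None]
    for i in range(n_ffn - 1, -1, -1):
        a = cache["acts"][i]
        grads[f"Wf{i}"] += a.T @ dh
        grads[f"bf{i}"] += dh.sum(axis=0)
        da = dh @ params[f"Wf{i}"].T
        if i > 0:
            dh = da * (cache["acts"][i] > 0)
        else:
            dz = da
    dmol = dz[:, :H]
    dAout = dmol[batch.atom_mol] / batch.atom_counts[batch.atom_mol][:, None]
    dZo = dAout * (cache["Aout"] > 0)
    grads["Wo"] += cache["Acat"].T @ dZo
    grads["bo"] += dZo.sum(axis=0)
    dAcat = dZo @ params["Wo"].T
    dS_final = dAcat[:, A.shape[1]:]
    dH = dS_final[dst]
    dH0_skip = np.zeros_like(cache["H0"])
    for t in range(cfg.depth - 1, -1, -1):
        H_t = cache["Hs"][t + 1]
        M_t = cache["Ms"][t]
        dPre = dH * (H_t > 0)
        dH0_skip += dPre
        grads["Wh"] += M_t.T @ dPre
        dM = dPre @ params["Wh"].T
        dS = _segment_sum(dM, src, n_atoms)
        dH = dS[dst] - dM[rev]
    dH0 = dH + dH0_skip
    dZ0 = dH0 * (cache["H0"] > 0)
    grads["Wi"] += cache["Ecat"].T @ dZ0
    grads["bi"] += dZ0.sum(axis=0)
    return grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce(logits: np.ndarray, y: np.ndarray) -> float:
    # softplus(logit) - y*logit, numerically stable
    return float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))


# ---------------------------------------------------------------------------
# trained model

@dataclass
class TrainedModel:
    params: _Params
    config: ModelConfig
    normalizer: Optional[Normalizer]
    descriptor_hash: Optional[str]
    descriptor_names: Optional[list[str]]
    loss_curve: list[float] = field(default_factory=list)
    val_curve: list[float] = field(default_factory=list)

    def _features(self, records: Sequence[MoleculeRecord]):
        graphs = [mol_to_graph(r) for r in records]
        desc = None
        if self.config.use_global_descriptors:
            calc = DescriptorCalculator(self.descriptor_names)
            desc = self.normalizer(calc.matrix(records))
        return graphs, desc

    def predict_proba(
        self,
        records: Sequence[MoleculeRecord],
        graphs: Optional[Sequence[MolGraph]] = None,
        desc: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        if graphs is None:
            graphs, desc = self._features(records)
        probs = np.empty(len(graphs))
        bs = max(self.config.batch_size, 1)
        for start in range(0, len(graphs), bs):
            sl = slice(start, start + bs)
            batch = _batch_graphs(graphs[sl])
            d = desc[sl] if desc is not None else None
            logits, _ = _forward(self.params, self.config, batch, d)
            probs[start:start + batch.n_mols] = _sigmoid(logits)
        return probs

    def save(self, path) -> None:
        cfg = asdict(self.config)
        meta = dict(config=cfg, descriptor_hash=self.descriptor_hash,
                    descriptor_names=self.descriptor_names,
                    loss_curve=self.loss_curve, val_curve=self.val_curve)
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        if self.normalizer is not None:
            arrays["norm_mean"] = self.normalizer.mean
            arrays["norm_std"] = self.normalizer.std
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        params = _Params({k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")})
        norm = None
        if "norm_mean" in data.files:
            norm = Normalizer(mean=data["norm_mean"], std=data["norm_std"])
        return cls(params=params, config=ModelConfig(**meta["config"]),
                   normalizer=norm, descriptor_hash=meta["descriptor_hash"],
                   descriptor_names=meta["descriptor_names"],
                   loss_curve=meta["loss_curve"], val_curve=meta["val_curve"])


def forward(
    model: TrainedModel, graph: MolGraph, descriptors: Optional[np.ndarray] = None
) -> float:
    """Probability of PBT for a single featurized molecule."""
    batch = _batch_graphs([graph])
    d = None
    if model.config.use_global_descriptors:
        if descriptors is None:
            raise ValueError("model expects a descriptor vector")
        d = np.asarray(descriptors, dtype=np.float64)[None, :]
    logits, _ = _forward(model.params, model.config, batch, d)
    return float(_sigmoid(logits)[0])


# ---------------------------------------------------------------------------
# training

def _lr_schedule(cfg: ModelConfig, steps_per_epoch: int) -> np.ndarray:
    total = cfg.epochs * steps_per_epoch
    warm = int(cfg.warmup_epochs * steps_per_epoch)
    warm = min(warm, total)
    lrs = np.empty(total)
    if warm > 0:
        lrs[:warm] = np.linspace(cfg.init_lr, cfg.max_lr, warm)
    decay_steps = total - warm
    if decay_steps > 0:
        gamma = (cfg.final_lr / cfg.max_lr) ** (1.0 / max(decay_steps - 1, 1))
        lrs[warm:] = cfg.max_lr * gamma ** np.arange(decay_steps)
    return lrs


def train(
    records: Sequence[MoleculeRecord],
    split: Optional[SplitResult],
    cfg: ModelConfig,
    graphs: Optional[dict[str, MolGraph]] = None,
    descriptors: Optional[dict[str, np.ndarray]] = None,
    val_fraction: float = 0.1,
) -> TrainedModel:
    """Minimize binary cross-entropy by mini-batch Adam.

    ``split`` selects the training (and optional validation) ids; when None,
    all records train and a validation fraction is carved out at random.
    Precomputed ``graphs``/``descriptors`` keyed by record id can be passed
    to avoid re-featurizing across runs.  When a validation set exists the
    best-validation-loss weights are retained (no early stopping: the full
    epoch budget always runs).
    """
    by_id = {r.id: r for r in records}
    if split is None:
        split = SplitResult(strategy="all", train_ids=[r.id for r in records], test_ids=[])
    if not split.val_ids and val_fraction > 0 and len(split.train_ids) >= 10:
        split = carve_validation(split, val_fraction, seed=cfg.seed)
    train_recs = [by_id[i] for i in split.train_ids]
    val_recs = [by_id[i] for i in split.val_ids]
    if not train_recs:
        raise ValueError("empty training set")
    if any(r.label is None for r in train_recs):
        raise ValueError("all training records need labels")
    labels = np.array([r.label for r in train_recs], dtype=float)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class training set")

    if graphs is None:
        graphs = {r.id: mol_to_graph(r) for r in records}
    norm = None
    desc_names = None
    desc_hash = None
    train_desc = val_desc = None
    if cfg.use_global_descriptors:
        calc = DescriptorCalculator(cfg.descriptor_names)
        desc_names = calc.names
        desc_hash = calc.hash
        if descriptors is None:
            descriptors = {r.id: calc(r) for r in records}
        raw_train = np.stack([descriptors[r.id] for r in train_recs])
        norm = fit_normalizer(raw_train)
        train_desc = norm(raw_train)
        if val_recs:
            val_desc = norm(np.stack([descriptors[r.id] for r in val_recs]))

    d_desc = train_desc.shape[1] if train_desc is not None else 0
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, d_desc, rng)
    model = TrainedModel(params=params, config=cfg, normalizer=norm,
                         descriptor_hash=desc_hash, descriptor_names=desc_names)

    train_graphs = [graphs[r.id] for r in train_recs]
    val_graphs = [graphs[r.id] for r in val_recs]
    val_labels = np.array([r.label for r in val_recs], dtype=float) if val_recs else None

    n = len(train_recs)
    bs = min(cfg.batch_size, n)
    steps_per_epoch = int(np.ceil(n / bs))
    lrs = _lr_schedule(cfg, steps_per_epoch)
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            batch = _batch_graphs([train_graphs[i] for i in idx])
            d = train_desc[idx] if train_desc is not None else None
            y = labels[idx]
            logits, cache = _forward(params, cfg, batch, d)
            epoch_loss += _bce(logits, y) * len(idx)
            dlogits = (_sigmoid(logits) - y) / len(idx)
            grads = _backward(params, cfg, cache, dlogits)
            lr = lrs[min(step, len(lrs) - 1)]
            step += 1
            for k in params:
                g = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                mhat = m_state[k] / (1 - beta1 ** step)
                vhat = v_state[k] / (1 - beta2 ** step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        model.loss_curve.append(epoch_loss / n)
        if val_recs:
            vb = _batch_graphs(val_graphs)
            vlogits, _ = _forward(params, cfg, vb, val_desc)
            vloss = _bce(vlogits, val_labels)
            model.val_curve.append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_params = {k: v.copy() for k, v in params.items()}
    if best_params is not None:
        model.params = _Params(best_params)
    return model


def predict(
    model: TrainedModel,
    records: Sequence[MoleculeRecord],
    graphs: Optional[Sequence[MolGraph]] = None,
    desc: Optional[np.ndarray] = None,
) -> list[MoleculeRecord]:
    """Attach probabilities and hard calls (p >= threshold -> PBT).

    Records that fail featurization are returned with a ``predict_failed``
    flag instead of aborting the batch.
    """
    from dataclasses import replace

    out = []
    ok_indices = []
    ok_records = []
    for i, rec in enumerate(records):
        try:
            mol_to_graph(rec)
            ok_indices.append(i)
            ok_records.append(rec)
            out.append(rec)
        except Exception:
            out.append(replace(rec, flags=rec.flags + ("predict_failed",)))
    if ok_records:
        probs = model.predict_proba(ok_records, graphs=graphs, desc=desc)
        for j, i in enumerate(ok_indices):
            out[i] = replace(out[i], prediction=float(probs[j]))
    return out


def hard_call(prob: float, threshold: float = 0.5) -> int:
    """Binary call; the boundary p == threshold maps to PBT (>= rule)."""
    return int(prob >= threshold)


def cross_validate(
    records: Sequence[MoleculeRecord],
    k: int = 10,
    cfg: ModelConfig = None,
    graphs: Optional[dict[str, MolGraph]] = None,
    descriptors: Optional[dict[str, np.ndarray]] = None,
) -> dict:
    """k-fold cross-validation with an 8:1:1-style rotation.

    Fold i is the test set, fold (i+1) mod k the validation set, the rest
    trains; every record is tested exactly once.  Returns per-fold metrics
    plus mean and standard deviation of AUC/accuracy/recall/specificity.
    """
    if cfg is None:
        cfg = ModelConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(records)
    if n < k:
        raise ValueError("need at least k records")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    folds = [sorted(perm[i::k]) for i in range(k)]
    if graphs is None:
        graphs = {r.id: mol_to_graph(r) for r in records}
    if cfg.use_global_descriptors and descriptors is None:
        calc = DescriptorCalculator(cfg.descriptor_names)
        descriptors = {r.id: calc(r) for r in records}
    fold_metrics = []
    for i in range(k):
        test_idx = set(folds[i])
        # with only two folds there is no third fold to validate on
        val_idx = set(folds[(i + 1) % k]) if k > 2 else set()
        train_ids = [records[j].id for j in range(n) if j not in test_idx and j not in val_idx]
        split = SplitResult(
            strategy=f"cv_fold_{i}",
            train_ids=train_ids,
            test_ids=[records[j].id for j in sorted(test_idx)],
            val_ids=[records[j].id for j in sorted(val_idx)],
        )
        model = train(records, split, cfg, graphs=graphs, descriptors=descriptors)
        test_recs = [records[j] for j in sorted(test_idx)]
        t_graphs = [graphs[r.id] for r in test_recs]
        t_desc = None
        if cfg.use_global_descriptors:
            t_desc = model.normalizer(np.stack([descriptors[r.id] for r in test_recs]))
        probs = model.predict_proba(test_recs, graphs=t_graphs, desc=t_desc)
        y = np.array([r.label for r in test_recs])
        calls = (probs >= cfg.threshold).astype(int)
        rep = evalkit.metrics(evalkit.confusion(y, calls))
        auc = evalkit.roc_auc(y, probs) if len(np.unique(y)) == 2 else np.nan
        fold_metrics.append({
            "fold": i, "n_test": len(test_recs),
            "test_ids": [r.id for r in test_recs], "auc": auc,
            "accuracy": rep.accuracy, "recall": rep.recall,
            "specificity": rep.specificity,
        })
    summary = {}
    for key in ("auc", "accuracy", "recall", "specificity"):
        vals = np.array([fm[key] for fm in fold_metrics], dtype=float)
        summary[key] = {"mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals))}
    return {"folds": fold_metrics, "summary": summary, "k": k}
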