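"""Directed message-passing neural network (D-MPNN) binary classifier.

The molecule is a graph: atoms are nodes, bonds are edges, and each bond is
expanded into two directed edges.  A hidden state lives on every directed
edge; at each message-passing step the state of edge u->v is refreshed from
the states of edges entering u, excluding its own reverse v->u (the
"directed" trick that stops messages bouncing straight back).  After
``depth`` steps the edge states are pooled onto atoms, averaged into a
molecule vector (mean readout, so the scale is independent of molecule
size), and a small feed-forward head with a sigmoid produces the activity
probability.

Update equations (all learned maps are shared across steps):

    h0_e   = ReLU(W_i [x_src(e) ; x_bond(e)])
    m_e(t) = sum_{e' : dst(e') = src(e), e' != rev(e)} h_e'(t)
    h_e(t+1) = ReLU(W_i[...] + W_h m_e(t))            # residual to the input
    h_v    = ReLU(W_o [x_v ; sum_{e : dst(e) = v} h_e])
    y      = sigmoid(FFN(mean_v h_v))

Training minimizes binary cross-entropy with Adam under a Noam-style warmup
learning-rate schedule.  Everything — forward pass, backpropagation, and the
optimizer — is implemented directly on NumPy arrays; gradients are verified
against finite differences in the test suite.  Ensembles are ``ensemble_size``
members trained from consecutive seeds; the ensemble probability is the
arithmetic mean of member probabilities.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import Dataset, MoleculeRecord

# --------------------------------------------------------------------------
# Featurization
# --------------------------------------------------------------------------

# One-hot layouts; the trailing slot of each one-hot block is the
# "other/unknown" catch-all.
ATOM_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si"]
ATOM_DEGREES = [0, 1, 2, 3, 4, 5]
ATOM_CHARGES = [-2, -1, 0, 1, 2]
ATOM_NUM_HS = [0, 1, 2, 3, 4]
ATOM_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]

ATOM_FDIM = (
    len(ATOM_ELEMENTS) + 1 + len(ATOM_DEGREES) + 1 + len(ATOM_CHARGES) + 1
    + len(ATOM_NUM_HS) + 1 + 1 + len(ATOM_HYBRIDIZATIONS) + 1 + 1
)
BOND_FDIM = len(BOND_TYPES) + 1 + 2 + len(BOND_STEREO) + 1


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    return (
        _one_hot(atom.GetSymbol(), ATOM_ELEMENTS)
        + _one_hot(atom.GetDegree(), ATOM_DEGREES)
        + _one_hot(atom.GetFormalCharge(), ATOM_CHARGES)
        + _one_hot(atom.GetTotalNumHs(), ATOM_NUM_HS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(atom.GetHybridization(), ATOM_HYBRIDIZATIONS)
        + [atom.GetMass() * 0.01]
    )


def _bond_features(bond: Chem.Bond) -> list[float]:
    return (
        _one_hot(bond.GetBondType(), BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
        + _one_hot(bond.GetStereo(), BOND_STEREO)
    )


@dataclass
class MolGraph:
    """Directed-edge graph representation of one molecule."""

    atom_features: np.ndarray  # (n_atoms, ATOM_FDIM)
    bond_features: np.ndarray  # (n_edges, BOND_FDIM), per directed edge
    edge_src: np.ndarray       # (n_edges,) source atom of each directed edge
    edge_dst: np.ndarray       # (n_edges,)
    rev_index: np.ndarray      # (n_edges,) index of the reverse directed edge

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]


def featurize(record: MoleculeRecord) -> MolGraph:
    """Build the directed graph of a standardized record.

    Each bond contributes two directed edges (u->v and v->u) carrying the
    same bond features; ``rev_index`` links the pair and is an involution.
    """
    smiles = record.canonical_smiles if isinstance(record, MoleculeRecord) else record
    if smiles is None:
        raise ValueError("unstandardized input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unstandardized input: {smiles!r}")
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("empty molecule")
    atom_f = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    bond_f, src, dst, rev = [], [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        e = len(src)
        bond_f.extend([bf, bf])
        src.extend([u, v])
        dst.extend([v, u])
        rev.extend([e + 1, e])
    return MolGraph(
        atom_features=atom_f,
        bond_features=(
            np.array(bond_f, dtype=np.float64)
            if bond_f else np.zeros((0, BOND_FDIM))
        ),
        edge_src=np.array(src, dtype=np.intp),
        edge_dst=np.array(dst, dtype=np.intp),
        rev_index=np.array(rev, dtype=np.intp),
    )


@dataclass
class _Batch:
    """Several MolGraphs packed into flat arrays with offset indices."""

    atom_features: np.ndarray
    bond_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    rev_index: np.ndarray
    mol_index: np.ndarray   # (n_atoms,) molecule id per atom
    atom_counts: np.ndarray  # (n_mols,)

    @property
    def n_mols(self) -> int:
        return self.atom_counts.shape[0]


def _make_batch(graphs: Sequence[MolGraph]) -> _Batch:
    atom_off = 0
    edge_off = 0
    af, bf, src, dst, rev, midx, counts = [], [], [], [], [], [], []
    for i, g in enumerate(graphs):
        af.append(g.atom_features)
        bf.append(g.bond_features)
        src.append(g.edge_src + atom_off)
        dst.append(g.edge_dst + atom_off)
        rev.append(g.rev_index + edge_off)
        midx.append(np.full(g.n_atoms, i, dtype=np.intp))
        counts.append(g.n_atoms)
        atom_off += g.n_atoms
        edge_off += g.n_edges
    return _Batch(
        atom_features=np.concatenate(af, axis=0),
        bond_features=np.concatenate(bf, axis=0),
        edge_src=np.concatenate(src),
        edge_dst=np.concatenate(dst),
        rev_index=np.concatenate(rev),
        mol_index=np.concatenate(midx),
        atom_counts=np.array(counts, dtype=np.float64),
    )


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class DMPNNConfig:
    """Hyperparameters; defaults are the model-building settings used
    throughout: depth-3 message passing, 300 hidden units, a two-layer
    feed-forward head with ReLU, 30 epochs, 10-member ensembles."""

    depth: int = 3
    hidden_size: int = 300
    ffn_layers: int = 2
    activation: str = "relu"
    epochs: int = 30
    ensemble_size: int = 10
    batch_size: int = 50
    seed: int = 0
    init_lr: float = 1e-4
    max_lr: float = 1e-3
    final_lr: float = 1e-4
    warmup_epochs: float = 2.0
    call_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("depth", "hidden_size", "ffn_layers", "epochs",
                     "ensemble_size", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.activation.lower() != "relu":
            raise ValueError("only the ReLU activation is supported")


# --------------------------------------------------------------------------
# Parameters, forward and backward passes
# --------------------------------------------------------------------------


def init_params(config: DMPNNConfig, rng: np.random.Generator) -> dict:
    """Xavier-uniform initialization of all learned maps."""
    h = config.hidden_size

    def xavier(shape):
        bound = math.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-bound, bound, size=shape)

    params = {
        "Wi": xavier((h, ATOM_FDIM + BOND_FDIM)),
        "bi": np.zeros(h),
        "Wh": xavier((h, h)),
        "bh": np.zeros(h),
        "Wo": xavier((h, ATOM_FDIM + h)),
        "bo": np.zeros(h),
    }
    for layer in range(config.ffn_layers):
        out_dim = 1 if layer == config.ffn_layers - 1 else h
        params[f"Wf{layer}"] = xavier((out_dim, h))
        params[f"bf{layer}"] = np.zeros(out_dim)
    return params


def _segment_sum(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, index, values)
    return out


def _forward(params: dict, batch: _Batch, config: DMPNNConfig, cache: Optional[dict] = None):
    """Probabilities for a batch; fills ``cache`` for backprop when given."""
    n_atoms = batch.atom_features.shape[0]
    E_in = np.concatenate(
        [batch.atom_features[batch.edge_src], batch.bond_features], axis=1
    )
    H0p = E_in @ params["Wi"].T + params["bi"]
    H = np.maximum(H0p, 0.0)
    steps = []
    for _ in range(config.depth - 1):
        S = _segment_sum(H, batch.edge_dst, n_atoms)
        M = S[batch.edge_src] - H[batch.rev_index]
        Hp = H0p + M @ params["Wh"].T + params["bh"]
        H_new = np.maximum(Hp, 0.0)
        steps.append((M, Hp))
        H = H_new
    S_final = _segment_sum(H, batch.edge_dst, n_atoms)
    A_in = np.concatenate([batch.atom_features, S_final], axis=1)
    Hap = A_in @ params["Wo"].T + params["bo"]
    Ha = np.maximum(Hap, 0.0)
    mol = _segment_sum(Ha, batch.mol_index, batch.n_mols) / batch.atom_counts[:, None]

    z = mol
    ffn = []
    for layer in range(config.ffn_layers):
        zp = z @ params[f"Wf{layer}"].T + params[f"bf{layer}"]
        if layer < config.ffn_layers - 1:
            z_new = np.maximum(zp, 0.0)
        else:
            z_new = zp
        ffn.append((z, zp))
        z = z_new
    logits = z[:, 0]
    probs = 1.0 / (1.0 + np.exp(-logits))
    if cache is not None:
        cache.update(
            E_in=E_in, H0p=H0p, steps=steps, H_final=H, A_in=A_in, Hap=Hap,
            mol=mol, ffn=ffn, probs=probs,
        )
    return probs


def _backward(params: dict, batch: _Batch, config: DMPNNConfig, cache: dict,
              dlogits: np.ndarray) -> dict:
    """Gradients of a scalar loss with given d(loss)/d(logit)."""
    n_atoms = batch.atom_features.shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dz = dlogits[:, None]
    for layer in reversed(range(config.ffn_layers)):
        z_in, zp = cache["ffn"][layer]
        if layer < config.ffn_layers - 1:
            dz = dz * (zp > 0.0)
        grads[f"Wf{layer}"] += dz.T @ z_in
        grads[f"bf{layer}"] += dz.sum(axis=0)
        dz = dz @ params[f"Wf{layer}"]
    dmol = dz

    dHa = dmol[batch.mol_index] / batch.atom_counts[batch.mol_index][:, None]
    dHap = dHa * (cache["Hap"] > 0.0)
    grads["Wo"] += dHap.T @ cache["A_in"]
    grads["bo"] += dHap.sum(axis=0)
    dA_in = dHap @ params["Wo"]
    dS_final = dA_in[:, ATOM_FDIM:]
    dH = dS_final[batch.edge_dst]

    dH0p = np.zeros_like(cache["H0p"])
    for t in reversed(range(config.depth - 1)):
        M, Hp = cache["steps"][t]
        dHp = dH * (Hp > 0.0)
        dH0p += dHp
        grads["Wh"] += dHp.T @ M
        grads["bh"] += dHp.sum(axis=0)
        dM = dHp @ params["Wh"]
        dS = _segment_sum(dM, batch.edge_src, n_atoms)
        dH = dS[batch.edge_dst] - dM[batch.rev_index]
    dH0p += dH * (cache["H0p"] > 0.0)
    grads["Wi"] += dH0p.T @ cache["E_in"]
    grads["bi"] += dH0p.sum(axis=0)
    return grads


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


class _NoamLR:
    """Linear warmup to max_lr, then exponential decay to final_lr."""

    def __init__(self, config: DMPNNConfig, steps_per_epoch: int):
        self.warmup_steps = max(1, int(config.warmup_epochs * steps_per_epoch))
        self.total_steps = max(self.warmup_steps + 1, config.epochs * steps_per_epoch)
        self.init_lr = config.init_lr
        self.max_lr = config.max_lr
        self.final_lr = config.final_lr
        decay_steps = self.total_steps - self.warmup_steps
        self.gamma = (self.final_lr / self.max_lr) ** (1.0 / decay_steps)

    def lr(self, step: int) -> float:
        if step < self.warmup_steps:
            frac = step / self.warmup_steps
            return self.init_lr + frac * (self.max_lr - self.init_lr)
        return self.max_lr * self.gamma ** (step - self.warmup_steps)


def train_member(
    dataset: Dataset,
    config: DMPNNConfig,
    member_seed: int,
    graphs: Optional[Sequence[MolGraph]] = None,
) -> dict:
    """Train one network member; reproducible per (dataset order, seed).

    Returns the parameter dict augmented with a ``"_meta"`` entry holding the
    loss history.  Raises ``ValueError("degenerate labels")`` unless both
    classes appear at least twice.
    """
    labels = np.array([r.label for r in dataset.records], dtype=np.float64)
    if np.any(np.isnan(labels)):
        raise ValueError("dataset must be fully labeled")
    n_pos = int(labels.sum())
    if n_pos < 2 or len(labels) - n_pos < 2:
        raise ValueError("degenerate labels: need at least 2 examples per class")
    if graphs is None:
        graphs = [featurize(r) for r in dataset.records]
    graphs = list(graphs)
    n = len(graphs)

    rng = np.random.default_rng(member_seed)
    params = init_params(config, rng)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    steps_per_epoch = math.ceil(n / config.batch_size)
    sched = _NoamLR(config, steps_per_epoch)

    step = 0
    losses = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = _make_batch([graphs[i] for i in idx])
            y = labels[idx]
            cache: dict = {}
            probs = _forward(params, batch, config, cache)
            epoch_loss += bce_loss(probs, y) * len(idx)
            dlogits = (probs - y) / len(idx)
            grads = _backward(params, batch, config, cache, dlogits)
            lr = sched.lr(step)
            step += 1
            for k in params:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                mhat = adam_m[k] / (1 - beta1**step)
                vhat = adam_v[k] / (1 - beta2**step)
                params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / n)
    params["_meta"] = {"loss_history": losses, "member_seed": member_seed}
    return params


def predict_member(
    params: dict,
    graphs: Sequence[MolGraph],
    config: DMPNNConfig,
    batch_size: int = 200,
) -> np.ndarray:
    """Member probabilities for a list of MolGraphs."""
    graphs = list(graphs)
    if not graphs:
        return np.zeros(0)
    out = []
    for start in range(0, len(graphs), batch_size):
        batch = _make_batch(graphs[start : start + batch_size])
        out.append(_forward(params, batch, config))
    return np.concatenate(out)


def dataset_digest(dataset: Dataset) -> str:
    """Content hash of (canonical_smiles, label) pairs, order-independent."""
    items = sorted((r.canonical_smiles or "", str(r.label)) for r in dataset.records)
    h = hashlib.sha256()
    for smi, lab in items:
        h.update(smi.encode())
        h.update(b"\t")
        h.update(lab.encode())
        h.update(b"\n")
    return h.hexdigest()


@dataclass
class TrainedEnsemble:
    members: list[dict]
    config: DMPNNConfig
    training_dataset_digest: str
    label_prevalence: float
    training_smiles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != self.config.ensemble_size:
            raise ValueError("member count must equal config.ensemble_size")


def train_ensemble(dataset: Dataset, config: DMPNNConfig) -> TrainedEnsemble:
    """Train ``ensemble_size`` members from seeds seed+0 .. seed+k-1."""
    graphs = [featurize(r) for r in dataset.records]
    members = [
        train_member(dataset, config, config.seed + i, graphs=graphs)
        for i in range(config.ensemble_size)
    ]
    labels = np.array([r.label for r in dataset.records], dtype=float)
    return TrainedEnsemble(
        members=members,
        config=config,
        training_dataset_digest=dataset_digest(dataset),
        label_prevalence=float(labels.mean()),
        training_smiles=[r.canonical_smiles for r in dataset.records],
    )


def predict(ensemble: TrainedEnsemble, queries: Dataset):
    """Ensemble predictions for standardized queries.

    Returns ``(probabilities, calls, member_std)``; the probability is the
    arithmetic mean over members, the call is 1 iff probability >= the
    configured threshold (ties called active), and ``member_std`` is the
    across-member standard deviation.
    """
    for rec in queries.records:
        if rec.canonical_smiles is None:
            raise ValueError(f"unstandardized query {rec.record_id!r}")
    graphs = [featurize(r) for r in queries.records]
    if not graphs:
        return np.zeros(0), np.zeros(0, dtype=int), np.zeros(0)
    member_probs = np.stack(
        [predict_member(m, graphs, ensemble.config) for m in ensemble.members]
    )
    probs = member_probs.mean(axis=0)
    std = member_probs.std(axis=0)
    calls = (probs >= ensemble.config.call_threshold).astype(int)
    return probs, calls, std


# --------------------------------------------------------------------------
# Serialization (one directory per model)
# --------------------------------------------------------------------------


def save_ensemble(ensemble: TrainedEnsemble, path, ad_metadata: Optional[dict] = None) -> None:
    """Write a model directory: config.json, meta.json, member_*.npz."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "config.json").write_text(json.dumps(asdict(ensemble.config), indent=1))
    meta = {
        "training_dataset_digest": ensemble.training_dataset_digest,
        "label_prevalence": ensemble.label_prevalence,
        "training_smiles": ensemble.training_smiles,
        "ad": ad_metadata or {},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for i, member in enumerate(ensemble.members):
        arrays = {k: v for k, v in member.items() if k != "_meta"}
        np.savez(path / f"member_{i:02d}.npz", **arrays)


def load_ensemble(path) -> tuple[TrainedEnsemble, dict]:
    """Load a model directory; returns (ensemble, ad_metadata)."""
    path = Path(path)
    config = DMPNNConfig(**json.loads((path / "config.json").read_text()))
    meta = json.loads((path / "meta.json").read_text())
    members = []
    for i in range(config.ensemble_size):
        with np.load(path / f"member_{i:02d}.npz") as npz:
            members.append({k: npz[k] for k in npz.files})
    ensemble = TrainedEnsemble(
        members=members,
        config=config,
        training_dataset_digest=meta["training_dataset_digest"],
        label_prevalence=meta["label_prevalence"],
        training_smiles=meta.get("training_smiles", []),
    )
    return ensemble, meta.get("ad", {})
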