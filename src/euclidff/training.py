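"""Combined energy/force loss, ADAM training loop and evaluation metrics.

The loss follows the force-matching convention used for machine-learned
force fields:

    L = (1 - beta) (E - E~)^2 + beta/(3n) sum_k sum_xyz (F_k - F~_k)^2

with trade-off beta (default 0.99, i.e. almost pure force matching).  The
learning rate decays exponentially by a fixed factor at a fixed step
interval; batch size is 1 for <= 1000 training structures and 10 beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import engine as eg
from .engine import Tensor
from .data import EV_TO_KCALMOL
from .graph import AtomicSystem, build_neighbors
from .network import ModelConfig, _forward_t, init_params, set_energy_statistics

__all__ = ["LabeledDataset", "TrainConfig", "loss", "train", "evaluate", "Metrics"]


@dataclass
class LabeledDataset:
    """Configurations with reference energies (eV) and forces (eV/A)."""

    systems: List[AtomicSystem]
    energies: np.ndarray
    forces: List[np.ndarray]
    units: str = "eV"

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if len(self.systems) != len(self.energies) or len(self.systems) != len(self.forces):
            raise ValueError("systems, energies and forces must have equal length")
        for s, f in zip(self.systems, self.forces):
            if np.shape(f) != (s.n_atoms, 3):
                raise ValueError("forces must be shaped n_atoms x 3 per system")
        if self.units not in ("eV", "kcal/mol"):
            raise ValueError("units must be 'eV' or 'kcal/mol'")

    def __len__(self):
        return len(self.systems)

    def to_ev(self) -> "LabeledDataset":
        """Convert kcal/mol labels to the internal eV unit system."""
        if self.units == "eV":
            return self
        c = 1.0 / EV_TO_KCALMOL
        return LabeledDataset(
            self.systems, self.energies * c, [f * c for f in self.forces], "eV"
        )

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(
            [self.systems[i] for i in indices],
            self.energies[list(indices)],
            [self.forces[i] for i in indices],
            self.units,
        )

    def force_std(self) -> float:
        """Standard deviation of all force components (label spread)."""
        return float(np.concatenate([f.ravel() for f in self.forces]).std())


@dataclass
class TrainConfig:
    beta: float = 0.99              # loss trade-off
    lr: float = 1e-3                # initial learning rate eta_0
    lr_decay: float = 0.7           # multiplicative decay factor
    lr_interval: int = 100_000      # steps between decays
    steps: int = 10_000
    valid_fraction: float = 0.1
    eval_interval: int = 1000       # best-validation checkpointing cadence
    seed: int = 0
    target_valid_loss: Optional[float] = None  # optional early-stop rule

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.steps <= 0:
            raise ValueError("steps must be positive")


def batch_size_rule(n_train: int) -> int:
    return 1 if n_train <= 1000 else 10


def learning_rate(step: int, cfg: TrainConfig) -> float:
    return cfg.lr * cfg.lr_decay ** (step // cfg.lr_interval)


def loss(pred: Tuple[float, np.ndarray], ref: Tuple[float, np.ndarray],
         beta: float) -> float:
    """Combined energy/force loss for one structure."""
    e, f = pred
    e_ref, f_ref = ref
    f = np.asarray(f, dtype=np.float64)
    f_ref = np.asarray(f_ref, dtype=np.float64)
    if f.shape != f_ref.shape:
        raise ValueError(f"force shape mismatch: {f.shape} vs {f_ref.shape}")
    n = f.shape[0]
    return float(
        (1.0 - beta) * (e - e_ref) ** 2
        + beta / (3.0 * n) * np.sum((f - f_ref) ** 2)
    )


def _loss_t(system, nl, params, e_ref, f_ref, beta, cfg):
    """Traced loss: differentiable w.r.t. parameters through the forces."""
    pos = Tensor(system.positions)
    e_tot, _ = _forward_t(pos, system, nl, params, cfg)
    grad = eg.backward(e_tot, pos)
    f_pred = eg.neg(grad)
    de = e_tot - e_ref
    df = f_pred - Tensor(f_ref)
    n = system.n_atoms
    return (1.0 - beta) * de * de + (beta / (3.0 * n)) * eg.sum_(df * df)


class Adam:
    """Plain ADAM on a named parameter dict."""

    def __init__(self, params: Dict[str, Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        new = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            new[k] = Tensor(p.data - lr * corr * self.m[k] / (np.sqrt(self.v[k]) + self.eps))
        return new


def train(params: Optional[Dict[str, Tensor]], dataset: LabeledDataset,
          cfg: TrainConfig, model_cfg: ModelConfig):
    """ADAM optimization of the combined loss; returns best-validation params.

    ``params=None`` draws fresh parameters (seeded) with the per-element
    energy shift/scale initialized from training-set statistics.  The run is
    deterministic given (seed, single thread, double precision).
    """
    dataset = dataset.to_ev()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(dataset))
    n_valid = max(1, int(round(cfg.valid_fraction * len(dataset)))) if len(dataset) > 1 else 0
    valid = dataset.subset(idx[:n_valid])
    tr = dataset.subset(idx[n_valid:])
    n_train = len(tr)
    if n_train == 0:
        raise ValueError("no training structures left after validation split")
    bs = batch_size_rule(n_train)

    if params is None:
        params = init_params(model_cfg, seed=cfg.seed)
        per_atom = np.array([e / s.n_atoms for e, s in zip(tr.energies, tr.systems)])
        set_energy_statistics(params, per_atom.mean(), max(per_atom.std(), 1e-3))

    # neighbor lists are geometry-fixed per structure: build once
    nls_tr = [build_neighbors(s, model_cfg.r_cut) for s in tr.systems]
    nls_va = [build_neighbors(s, model_cfg.r_cut) for s in valid.systems]

    opt = Adam(params)
    history = {"step": [], "train_loss": [], "valid_loss": [], "lr": []}
    best = {k: Tensor(p.data.copy()) for k, p in params.items()}
    best_loss = np.inf
    order = rng.permutation(n_train)
    cursor = 0

    def validation_loss(p):
        if len(valid) == 0:
            return np.nan
        tot = 0.0
        for s, nl, e_ref, f_ref in zip(valid.systems, nls_va, valid.energies, valid.forces):
            tot += float(_loss_t(s, nl, p, e_ref, f_ref, cfg.beta, model_cfg).data)
        return tot / len(valid)

    vl0 = validation_loss(params)
    history["step"].append(0)
    history["train_loss"].append(np.nan)
    history["valid_loss"].append(vl0)
    history["lr"].append(cfg.lr)
    if not np.isnan(vl0):
        best_loss = vl0

    names = list(params)
    for step in range(cfg.steps):
        grads = {k: np.zeros_like(params[k].data) for k in names}
        batch_loss = 0.0
        for _ in range(bs):
            if cursor == n_train:
                order = rng.permutation(n_train)
                cursor = 0
            k = order[cursor]
            cursor += 1
            lt = _loss_t(tr.systems[k], nls_tr[k], params,
                         tr.energies[k], tr.forces[k], cfg.beta, model_cfg)
            if not np.isfinite(lt.data):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (structure {k}); aborting"
                )
            batch_loss += float(lt.data)
            gs = eg.backward(lt, [params[k2] for k2 in names])
            for k2, g in zip(names, gs):
                grads[k2] += g.data
        for k2 in names:
            grads[k2] /= bs
        params = opt.step(params, grads, learning_rate(step, cfg))

        if (step + 1) % cfg.eval_interval == 0 or step + 1 == cfg.steps:
            vl = validation_loss(params)
            history["step"].append(step + 1)
            history["train_loss"].append(batch_loss / bs)
            history["valid_loss"].append(vl)
            history["lr"].append(learning_rate(step, cfg))
            if not np.isnan(vl) and vl < best_loss:
                best_loss = vl
                best = {k: Tensor(p.data.copy()) for k, p in params.items()}
            if cfg.target_valid_loss is not None and vl <= cfg.target_valid_loss:
                break

    if best_loss is np.inf or np.isinf(best_loss):
        best = params
    return best, history


@dataclass
class Metrics:
    energy_mae: float
    force_mae: float
    per_atom_errors: List[np.ndarray]       # eps_i = ||F_i - F~_i||_2 per atom
    per_structure_errors: np.ndarray        # mean eps over each structure
    units: str = "eV"

    def in_kcalmol(self) -> "Metrics":
        if self.units == "kcal/mol":
            return self
        c = EV_TO_KCALMOL
        return Metrics(
            self.energy_mae * c, self.force_mae * c,
            [e * c for e in self.per_atom_errors],
            self.per_structure_errors * c, "kcal/mol",
        )


def evaluate(potential, dataset: LabeledDataset, units: str = "eV") -> Metrics:
    """Energy/force MAEs and the per-structure force-error distribution."""
    dataset = dataset.to_ev()
    e_errs, f_errs, per_atom, per_struct = [], [], [], []
    for s, e_ref, f_ref in zip(dataset.systems, dataset.energies, dataset.forces):
        e, f = potential.energy_and_forces(s)
        e_errs.append(abs(e - e_ref))
        f_errs.append(np.abs(f - f_ref).ravel())
        eps = np.linalg.norm(f - f_ref, axis=1)
        per_atom.append(eps)
        per_struct.append(eps.mean())
    m = Metrics(
        energy_mae=float(np.mean(e_errs)),
        force_mae=float(np.concatenate(f_errs).mean()),
        per_atom_errors=per_atom,
        per_structure_errors=np.array(per_struct),
    )
    return m.in_kcalmol() if units == "kcal/mol" else m
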