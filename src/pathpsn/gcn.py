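"""Per-pathway GraphSAGE node classifiers and the majority-vote ensemble.

Each signature network trains its own small graph neural classifier: two
rounds of weighted-mean neighborhood aggregation (GraphSAGE with a
self/neighbor weight split), hidden width 16, ReLU, dropout, and a linear
softmax head, trained with Adam and cross-entropy on the training nodes
with early stopping on validation loss.  The implementation is plain
numpy with hand-written gradients: the graphs have tens of nodes, so a
deep-learning framework would add nothing but nondeterminism.

Node features deliberately avoid label leakage: training nodes carry
their class as a one-hot plus a known-indicator of 1; validation and
test nodes carry a zero vector with indicator 0.  A model is *accepted*
only when its validation MCC reaches the configured threshold; only
accepted models vote, and the ensemble assigns each unknown patient the
majority class (ties broken by the higher mean predicted probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .metrics import matthews_corrcoef
from .psn import SimilarityNetwork

logger = logging.getLogger(__name__)

N_FEATURES = 3  # one-hot class (2) + known-indicator (1)


@dataclass
class NodeFeatureSet:
    """Feature matrix, integer labels and roles over a network's nodes.

    ``y`` is the class index (0/1) for every node whose label is known,
    -1 otherwise; ``roles`` maps each patient to train / validation /
    test.  Validation and test nodes never carry their class in ``x``.
    """

    patient_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    roles: dict[str, str]
    class_order: tuple[str, str]

    def mask(self, role: str) -> np.ndarray:
        return np.array([self.roles.get(p) == role for p in self.patient_ids])


def build_node_features(network: SimilarityNetwork,
                        labels: pd.Series | dict,
                        roles: dict[str, str],
                        class_order: tuple[str, str] | None = None
                        ) -> NodeFeatureSet:
    """Encode node features with the class one-hot masked off non-train nodes."""
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    if class_order is None:
        class_order = tuple(sorted(labels.dropna().unique()))
    if len(class_order) != 2:
        raise ValueError(f"expected two classes, got {class_order}")
    n = network.n_patients
    x = np.zeros((n, N_FEATURES))
    y = np.full(n, -1, dtype=int)
    for i, pid in enumerate(network.patient_ids):
        role = roles.get(pid, "test")
        if pid in labels.index and not pd.isna(labels.get(pid)):
            y[i] = class_order.index(labels[pid])
        if role == "train":
            if y[i] < 0:
                raise ValueError(f"training node {pid!r} has no label")
            x[i, y[i]] = 1.0
            x[i, 2] = 1.0
    return NodeFeatureSet(patient_ids=list(network.patient_ids), x=x, y=y,
                          roles=dict(roles), class_order=class_order)


@dataclass
class TrainedPSNModel:
    """Learned parameters and validation verdict for one network's GCN."""

    pathway_id: str
    params: dict[str, np.ndarray]
    class_order: tuple[str, str]
    validation_mcc: float
    accepted: bool
    seed: int
    epochs_run: int
    direction: str = "activated"

    def to_jsonable(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "class_order": list(self.class_order),
            "validation_mcc": self.validation_mcc,
            "accepted": self.accepted,
            "seed": self.seed,
            "epochs_run": self.epochs_run,
            "direction": self.direction,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "TrainedPSNModel":
        return cls(pathway_id=d["pathway_id"],
                   params={k: np.asarray(v) for k, v in d["params"].items()},
                   class_order=tuple(d["class_order"]),
                   validation_mcc=float(d["validation_mcc"]),
                   accepted=bool(d["accepted"]),
                   seed=int(d["seed"]),
                   epochs_run=int(d["epochs_run"]),
                   direction=d.get("direction", "activated"))


def _row_normalized_adjacency(w: np.ndarray) -> np.ndarray:
    """Neighbor weights normalized to sum to 1 per node (zero rows stay zero)."""
    sums = w.sum(axis=1, keepdims=True)
    return np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)


def _init_params(rng: np.random.Generator, hidden: int) -> dict[str, np.ndarray]:
    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return {
        "Ws1": glorot(N_FEATURES, hidden), "Wn1": glorot(N_FEATURES, hidden),
        "b1": np.zeros(hidden),
        "Ws2": glorot(hidden, hidden), "Wn2": glorot(hidden, hidden),
        "b2": np.zeros(hidden),
        "Wo": glorot(hidden, 2), "bo": np.zeros(2),
    }


def _forward(params: dict, x: np.ndarray, a: np.ndarray,
             dropout: float = 0.0, rng: np.random.Generator | None = None
             ) -> tuple[np.ndarray, dict]:
    """Two GraphSAGE layers + linear head; returns logits and a cache."""
    cache: dict = {"x": x}
    ax = a @ x
    z1 = x @ params["Ws1"] + ax @ params["Wn1"] + params["b1"]
    h1 = np.maximum(z1, 0.0)
    if dropout > 0 and rng is not None:
        m1 = rng.random(h1.shape) >= dropout
        d1 = h1 * m1 / (1.0 - dropout)
    else:
        m1 = None
        d1 = h1
    ad1 = a @ d1
    z2 = d1 @ params["Ws2"] + ad1 @ params["Wn2"] + params["b2"]
    h2 = np.maximum(z2, 0.0)
    if dropout > 0 and rng is not None:
        m2 = rng.random(h2.shape) >= dropout
        d2 = h2 * m2 / (1.0 - dropout)
    else:
        m2 = None
        d2 = h2
    logits = d2 @ params["Wo"] + params["bo"]
    cache.update(ax=ax, z1=z1, m1=m1, d1=d1, ad1=ad1, z2=z2, m2=m2, d2=d2,
                 dropout=dropout)
    return logits, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grads(params: dict, cache: dict, logits: np.ndarray,
                    a: np.ndarray, y: np.ndarray, mask: np.ndarray
                    ) -> tuple[float, dict]:
    probs = _softmax(logits)
    n = int(mask.sum())
    eps = 1e-12
    loss = -float(np.log(probs[mask, y[mask]] + eps).mean())
    dlogits = np.zeros_like(probs)
    dlogits[mask] = probs[mask]
    dlogits[mask, y[mask]] -= 1.0
    dlogits /= n
    d2, d1, x = cache["d2"], cache["d1"], cache["x"]
    grads = {"Wo": d2.T @ dlogits, "bo": dlogits.sum(axis=0)}
    dd2 = dlogits @ params["Wo"].T
    if cache["m2"] is not None:
        dh2 = dd2 * cache["m2"] / (1.0 - cache["dropout"])
    else:
        dh2 = dd2
    dz2 = dh2 * (cache["z2"] > 0)
    grads["Ws2"] = d1.T @ dz2
    grads["Wn2"] = cache["ad1"].T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dd1 = dz2 @ params["Ws2"].T + a.T @ (dz2 @ params["Wn2"].T)
    if cache["m1"] is not None:
        dh1 = dd1 * cache["m1"] / (1.0 - cache["dropout"])
    else:
        dh1 = dd1
    dz1 = dh1 * (cache["z1"] > 0)
    grads["Ws1"] = x.T @ dz1
    grads["Wn1"] = cache["ax"].T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_model(network: SimilarityNetwork, features: NodeFeatureSet,
                config: RunConfig) -> TrainedPSNModel:
    """Train and gate one network's GraphSAGE classifier.

    Cross-entropy on the training nodes, early stopping on validation
    loss with the configured patience; the returned model is accepted iff
    its validation MCC reaches ``config.acceptance_mcc``.
    """
    train_mask = features.mask("train")
    val_mask = features.mask("validation")
    y = features.y
    for cls in (0, 1):
        if not np.any(y[train_mask] == cls):
            raise ValueError(
                f"class {features.class_order[cls]!r} absent from training nodes")
    seed = config.derive_seed(f"gcn:{network.pathway_id}")
    rng = np.random.default_rng(seed)
    params = _init_params(rng, config.gcn_hidden)
    a = _row_normalized_adjacency(network.weights)
    opt = _Adam(params, config.gcn_learning_rate)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    patience_left = config.gcn_patience
    epochs_run = 0
    for epoch in range(config.gcn_max_epochs):
        logits, cache = _forward(params, features.x, a,
                                 dropout=config.gcn_dropout, rng=rng)
        _, grads = _loss_and_grads(params, cache, logits, a, y, train_mask)
        opt.step(params, grads)
        epochs_run = epoch + 1
        eval_logits, _ = _forward(params, features.x, a)
        probs = _softmax(eval_logits)
        if val_mask.any():
            val_loss = -float(np.log(
                probs[val_mask, y[val_mask]] + 1e-12).mean())
        else:
            val_loss = -float(np.log(
                probs[train_mask, y[train_mask]] + 1e-12).mean())
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            patience_left = config.gcn_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    eval_logits, _ = _forward(best_params, features.x, a)
    pred = eval_logits.argmax(axis=1)
    if val_mask.any():
        val_mcc = matthews_corrcoef(y[val_mask], pred[val_mask])
    else:
        val_mcc = matthews_corrcoef(y[train_mask], pred[train_mask])
    accepted = bool(val_mcc >= config.acceptance_mcc)
    logger.info("train_model[%s]: epochs=%d val_mcc=%.3f accepted=%s",
                network.pathway_id, epochs_run, val_mcc, accepted)
    return TrainedPSNModel(pathway_id=network.pathway_id, params=best_params,
                           class_order=features.class_order,
                           validation_mcc=float(val_mcc), accepted=accepted,
                           seed=seed, epochs_run=epochs_run,
                           direction=network.direction)


def predict_unknowns(model: TrainedPSNModel, network: SimilarityNetwork,
                     features: NodeFeatureSet,
                     unknown_ids: list[str]) -> pd.DataFrame:
    """Class vote and probability for each unknown patient in the network."""
    if not model.accepted:
        raise ValueError(f"model for {model.pathway_id} was not accepted; "
                         "rejected models must not vote")
    a = _row_normalized_adjacency(network.weights)
    logits, _ = _forward(model.params, features.x, a)
    probs = _softmax(logits)
    rows = []
    for pid in unknown_ids:
        i = features.patient_ids.index(pid)
        cls = int(probs[i].argmax())
        rows.append({"patient": pid, "pathway_id": model.pathway_id,
                     "vote": model.class_order[cls],
                     "probability": float(probs[i, cls]),
                     "p_" + model.class_order[0]: float(probs[i, 0]),
                     "p_" + model.class_order[1]: float(probs[i, 1])})
    return pd.DataFrame(rows)


@dataclass
class EnsemblePrediction:
    """Majority-vote outcome for the unknown patients."""

    votes: pd.DataFrame  # one row per (patient, pathway) vote
    predictions: pd.Series  # patient -> class
    agreement: pd.Series  # patient -> winning-vote fraction

    def to_jsonable(self) -> dict:
        return {"predictions": self.predictions.to_dict(),
                "agreement": self.agreement.to_dict(),
                "votes": self.votes.to_dict(orient="records")}


def ensemble_vote(votes: pd.DataFrame) -> EnsemblePrediction:
    """Combine per-network votes into the final class per patient.

    Majority class wins; an exact tie goes to the class with the higher
    mean predicted probability across the models that voted for it.
    """
    if votes.empty:
        raise ValueError("no usable signature networks: zero accepted models voted")
    predictions = {}
    agreement = {}
    for patient, group in votes.groupby("patient"):
        counts = group["vote"].value_counts()
        top = counts.max()
        tied = counts[counts == top].index.tolist()
        if len(tied) == 1:
            winner = tied[0]
        else:
            mean_prob = {c: group.loc[group["vote"] == c, "probability"].mean()
                         for c in tied}
            winner = max(sorted(tied), key=lambda c: mean_prob[c])
        predictions[patient] = winner
        agreement[patient] = float(counts[winner] / counts.sum())
    return EnsemblePrediction(votes=votes,
                              predictions=pd.Series(predictions, name="predicted"),
                              agreement=pd.Series(agreement, name="agreement"))
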