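"""Gender-age relation graph (GARG) and complex-valued embedding learning.

Participants, their integer ages, and their gender tokens form the entities
of a small knowledge graph with relations ``AgeIs`` and ``GenderIs`` (and
optionally ``HasLabel`` for training-fold emotion classes). Each entity and
relation receives a complex embedding of shared dimension K; a triple
(s, r, o) is scored by the real part of the trilinear Hermitian product

    f(s, r, o) = Re(<w_r, e_s, conj(e_o)>)
              = <Re w, Re s, Re o> + <Re w, Im s, Im o>
              + <Im w, Re s, Im o> - <Im w, Im s, Re o>.

Training maximizes the softmax likelihood of each observed triple against
sampled corruptions of its object and of its subject (negatives are filtered
so that no corruption is itself an observed positive), with an L2 penalty on
all embedding components. The real parts of the trained participant
embeddings are exported as per-subject covariate features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import SubjectMeta

__all__ = [
    "KnowledgeGraph",
    "ComplExModel",
    "build_triples",
    "complex_score",
    "conditional_prob",
    "sample_negatives",
    "training_loss",
    "filtered_ranking",
    "extract_embeddings",
    "write_triples",
    "save_model",
    "load_model",
    "train_garg",
    "GargEmbedder",
]


@dataclass
class KnowledgeGraph:
    """Entity/relation vocabularies plus observed (head, relation, tail) triples."""

    entities: list[str]
    relations: list[str]
    triples: list[tuple[int, int, int]]
    entity_index: dict[str, int] = field(init=False)
    relation_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.entity_index = {e: i for i, e in enumerate(self.entities)}
        self.relation_index = {r: i for i, r in enumerate(self.relations)}
        if len(self.entity_index) != len(self.entities):
            raise ValueError("duplicate entity names")
        if len(set(self.triples)) != len(self.triples):
            raise ValueError("duplicate triples")
        ne, nr = len(self.entities), len(self.relations)
        for h, r, t in self.triples:
            if not (0 <= h < ne and 0 <= t < ne and 0 <= r < nr):
                raise ValueError(f"triple {(h, r, t)} references out-of-vocabulary index")
        # Filter sets for negative sampling and filtered ranking.
        self._tails_of: dict[tuple[int, int], set[int]] = {}
        self._heads_of: dict[tuple[int, int], set[int]] = {}
        for h, r, t in self.triples:
            self._tails_of.setdefault((h, r), set()).add(t)
            self._heads_of.setdefault((r, t), set()).add(h)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    def observed_completions(self, triple: tuple[int, int, int], direction: str) -> set[int]:
        """Entity indices that complete the triple as an observed positive."""
        h, r, t = triple
        if direction == "object":
            return self._tails_of.get((h, r), set())
        if direction == "subject":
            return self._heads_of.get((r, t), set())
        raise ValueError(f"direction must be 'object' or 'subject', got {direction!r}")


@dataclass
class ComplExModel:
    """Complex entity/relation embeddings of shared dimension K (stored as real pairs)."""

    entities: list[str]
    relations: list[str]
    ent_re: np.ndarray
    ent_im: np.ndarray
    rel_re: np.ndarray
    rel_im: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.ent_re, self.ent_im, self.rel_re, self.rel_im):
            if not np.all(np.isfinite(a)):
                raise ValueError("embedding components must be finite")
        if self.ent_re.shape != self.ent_im.shape or self.rel_re.shape != self.rel_im.shape:
            raise ValueError("real/imaginary shapes must match")
        if self.ent_re.shape[1] != self.rel_re.shape[1]:
            raise ValueError("entities and relations must share the embedding dimension K")

    @property
    def dim(self) -> int:
        return self.ent_re.shape[1]

    def entity_complex(self, idx: int) -> np.ndarray:
        return self.ent_re[idx] + 1j * self.ent_im[idx]


def build_triples(
    subjects: Sequence[SubjectMeta],
    train_labels: Mapping[str, str] | None = None,
) -> KnowledgeGraph:
    """Construct the gender-age graph from participant metadata.

    Each participant contributes one ``AgeIs`` triple to its integer-age
    entity and one ``GenderIs`` triple to its gender entity; distinct age
    values and the two genders are single shared entities. If
    ``train_labels`` maps subject ids to class tokens, additional
    ``HasLabel`` triples are added for exactly those subjects (callers must
    restrict the map to training-fold subjects to avoid label leakage).
    """
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in subjects")
    entities: list[str] = list(ids)
    for s in subjects:
        age_ent = f"age:{int(s.age)}"
        if age_ent not in entities:
            entities.append(age_ent)
    for g in ("F", "M"):
        if any(s.gender == g for s in subjects):
            entities.append(f"gender:{g}")
    relations = ["AgeIs", "GenderIs"]
    if train_labels:
        relations.append("HasLabel")
        for lab in sorted({str(v) for v in train_labels.values()}):
            entities.append(f"label:{lab}")

    eidx = {e: i for i, e in enumerate(entities)}
    triples: list[tuple[int, int, int]] = []
    for s in subjects:
        triples.append((eidx[s.subject_id], 0, eidx[f"age:{int(s.age)}"]))
        triples.append((eidx[s.subject_id], 1, eidx[f"gender:{s.gender}"]))
    if train_labels:
        for sid, lab in train_labels.items():
            if sid not in eidx:
                raise ValueError(f"train_labels references unknown subject {sid!r}")
            triples.append((eidx[sid], 2, eidx[f"label:{lab}"]))
    return KnowledgeGraph(entities=entities, relations=relations, triples=triples)


def complex_score(model: ComplExModel, triple: tuple[int, int, int]) -> float:
    """Score one triple: Re(<w_r, e_s, conj(e_o)>) via the 4-term real expansion."""
    h, r, t = triple
    if not (0 <= h < len(model.entities) and 0 <= t < len(model.entities)):
        raise IndexError(f"entity index out of vocabulary in triple {triple}")
    if not 0 <= r < len(model.relations):
        raise IndexError(f"relation index {r} out of vocabulary")
    rw, iw = model.rel_re[r], model.rel_im[r]
    rs, is_ = model.ent_re[h], model.ent_im[h]
    ro, io = model.ent_re[t], model.ent_im[t]
    return float(
        np.sum(rw * rs * ro) + np.sum(rw * is_ * io)
        + np.sum(iw * rs * io) - np.sum(iw * is_ * ro)
    )


def _candidate_scores(
    model: ComplExModel, triple: tuple[int, int, int],
    candidates: np.ndarray, direction: str,
) -> np.ndarray:
    """Vectorized scores of a triple with one slot replaced by each candidate."""
    h, r, t = triple
    rw, iw = model.rel_re[r], model.rel_im[r]
    if direction == "object":
        rs, is_ = model.ent_re[h], model.ent_im[h]
        ro, io = model.ent_re[candidates], model.ent_im[candidates]
        return (ro @ (rw * rs) + io @ (rw * is_) + io @ (iw * rs) - ro @ (iw * is_))
    rs, is_ = model.ent_re[candidates], model.ent_im[candidates]
    ro, io = model.ent_re[t], model.ent_im[t]
    return (rs @ (rw * ro) + is_ @ (rw * io) + rs @ (iw * io) - is_ @ (iw * ro))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def conditional_prob(
    model: ComplExModel,
    triple: tuple[int, int, int],
    negatives: Sequence[int],
    direction: str = "object",
) -> float:
    """Softmax probability of the true completion over {true} ∪ negatives.

    The candidate set is the observed completion plus the sampled
    corruptions; probabilities over that set sum to one, so the returned
    value lies in (0, 1].
    """
    h, r, t = triple
    true_ent = t if direction == "object" else h
    negatives = np.asarray(list(negatives), dtype=int)
    if np.any(negatives == true_ent):
        raise ValueError("true completion present among negatives")
    candidates = np.concatenate(([true_ent], negatives))
    p = _softmax(_candidate_scores(model, triple, candidates, direction))
    return float(p[0])


def sample_negatives(
    graph: KnowledgeGraph,
    triple: tuple[int, int, int],
    n: int,
    direction: str = "object",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample ``n`` filtered corruption entities uniformly without replacement.

    Candidates are all entities that do NOT complete the triple as an
    observed positive (the "filtered" protocol). If fewer than ``n`` valid
    candidates exist, all of them are returned with a warning.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    positives = graph.observed_completions(triple, direction)
    valid = np.array([e for e in range(graph.n_entities) if e not in positives], dtype=int)
    if valid.size == 0:
        raise ValueError("no valid corruption candidates: every entity is a positive")
    if valid.size < n:
        warnings.warn(
            f"only {valid.size} valid corruption candidates (< requested {n}); returning all"
        )
        return rng.permutation(valid)
    return rng.choice(valid, size=n, replace=False)


def training_loss(
    model: ComplExModel,
    graph: KnowledgeGraph,
    negatives: Mapping[tuple[int, str], Sequence[int]],
    lam: float,
) -> float:
    """Negative log-likelihood of observed triples plus L2 penalty.

    ``negatives[(i, direction)]`` holds the sampled corruption entities for
    triple ``i`` in each of the two directions. The penalty sums squared real
    and imaginary components of every embedding, weighted by ``lam``.
    """
    loss = 0.0
    for i, triple in enumerate(graph.triples):
        for direction in ("object", "subject"):
            p = conditional_prob(model, triple, negatives[(i, direction)], direction)
            loss -= np.log(p)
    penalty = lam * (
        np.sum(model.ent_re**2) + np.sum(model.ent_im**2)
        + np.sum(model.rel_re**2) + np.sum(model.rel_im**2)
    )
    loss += penalty
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    return float(loss)


def filtered_ranking(
    model: ComplExModel, graph: KnowledgeGraph
) -> dict[str, object]:
    """Filtered ranking of every observed triple in both directions.

    For each triple and direction, the true completion is ranked against all
    entities that are not themselves observed positives for that slot. Tied
    scores receive the mean rank of their tie block. Reports MRR, Hits@1 and
    Hits@3 overall and broken down by (relation, direction).
    """
    ranks: list[float] = []
    by_key: dict[tuple[str, str], list[float]] = {}
    for triple in graph.triples:
        h, r, t = triple
        for direction in ("object", "subject"):
            true_ent = t if direction == "object" else h
            positives = graph.observed_completions(triple, direction)
            candidates = np.array(
                [true_ent] + [e for e in range(graph.n_entities)
                              if e not in positives and e != true_ent],
                dtype=int,
            )
            scores = _candidate_scores(model, triple, candidates, direction)
            true_score = scores[0]
            greater = int(np.sum(scores > true_score))
            ties = int(np.sum(scores == true_score))  # includes the true completion
            rank = greater + (ties + 1) / 2.0
            ranks.append(rank)
            by_key.setdefault((graph.relations[r], direction), []).append(rank)

    def summarize(rs: list[float]) -> dict[str, float]:
        a = np.asarray(rs)
        return {
            "mrr": float(np.mean(1.0 / a)),
            "hits@1": float(np.mean(a <= 1)),
            "hits@3": float(np.mean(a <= 3)),
            "mean_rank": float(a.mean()),
            "n": int(a.size),
        }

    report: dict[str, object] = summarize(ranks)
    report["by_relation"] = {
        f"{rel}/{direction}": summarize(rs) for (rel, direction), rs in by_key.items()
    }
    report["ranks"] = ranks
    return report


def extract_embeddings(
    model: ComplExModel, subjects: Sequence[SubjectMeta]
) -> pd.DataFrame:
    """Real parts of participant entity embeddings, one row per subject."""
    idx = {e: i for i, e in enumerate(model.entities)}
    rows = []
    for s in subjects:
        if s.subject_id not in idx:
            raise KeyError(f"subject {s.subject_id!r} has no participant entity in the model")
        rows.append(model.ent_re[idx[s.subject_id]])
    return pd.DataFrame(
        np.asarray(rows), index=[s.subject_id for s in subjects],
        columns=[f"g{k}" for k in range(model.dim)],
    )


class GargEmbedder(BaseEstimator, TransformerMixin):
    """Learn complex gender-age graph embeddings; transform subjects to real-part rows.

    Parameters
    ----------
    dim : int, default 50
        Embedding dimension K (entities need a reasonably high-dimensional
        space to be distinguishable).
    n_negatives : int, default 10
        Corruptions sampled per triple per direction per epoch.
    lam : float, default 1e-3
        L2 trade-off on all embedding components.
    epochs : int, default 300
        Full-batch passes; negatives are resampled every epoch.
    lr : float, default 1e-2
        Adagrad learning rate.
    seed : int, default 0
        Controls Gaussian initialization (scale 1/sqrt(K)) and negative
        sampling.

    Attributes
    ----------
    graph_ : KnowledgeGraph
    model_ : ComplExModel
    loss_history_ : list of float
        Monte-Carlo training loss per epoch.
    """

    def __init__(self, dim: int = 50, n_negatives: int = 10, lam: float = 1e-3,
                 epochs: int = 300, lr: float = 1e-2, seed: int = 0):
        self.dim = dim
        self.n_negatives = n_negatives
        self.lam = lam
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def fit(self, subjects: Sequence[SubjectMeta],
            train_labels: Mapping[str, str] | None = None) -> "GargEmbedder":
        if self.dim < 1 or self.n_negatives < 1 or self.lam < 0:
            raise ValueError("invalid GargEmbedder configuration")
        self.graph_ = build_triples(subjects, train_labels)
        self.model_, self.loss_history_ = _train(
            self.graph_, dim=self.dim, n_negatives=self.n_negatives, lam=self.lam,
            epochs=self.epochs, lr=self.lr, seed=self.seed,
        )
        self._subjects = list(subjects)
        return self

    def transform(self, subjects: Sequence[SubjectMeta]) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("GargEmbedder is not fitted")
        return extract_embeddings(self.model_, subjects).to_numpy()


def _train(
    graph: KnowledgeGraph, dim: int, n_negatives: int, lam: float,
    epochs: int, lr: float, seed: int,
) -> tuple[ComplExModel, list[float]]:
    """Full-batch Adagrad on the negative-sampling softmax likelihood."""
    rng = np.random.default_rng(seed)
    ne, nr = len(graph.entities), len(graph.relations)
    scale = 1.0 / np.sqrt(dim)
    params = {
        "ent_re": rng.normal(0, scale, (ne, dim)),
        "ent_im": rng.normal(0, scale, (ne, dim)),
        "rel_re": rng.normal(0, scale, (nr, dim)),
        "rel_im": rng.normal(0, scale, (nr, dim)),
    }
    accum = {k: np.zeros_like(v) for k, v in params.items()}
    eps = 1e-8
    history: list[float] = []

    for _ in range(epochs):
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        model = ComplExModel(graph.entities, graph.relations, **params)
        epoch_loss = 0.0
        for triple in graph.triples:
            h, r, t = triple
            for direction in ("object", "subject"):
                negs = sample_negatives(graph, triple, n_negatives, direction, rng)
                true_ent = t if direction == "object" else h
                cands = np.concatenate(([true_ent], negs))
                scores = _candidate_scores(model, triple, cands, direction)
                p = _softmax(scores)
                epoch_loss -= np.log(p[0])
                # dL/df_c = p_c - 1[c is true completion]
                df = p.copy()
                df[0] -= 1.0
                # Chain rule through f's partials:
                # df/dRw = Rs*Ro + Is*Io        df/dIw = Rs*Io - Is*Ro
                # df/dRs = Rw*Ro + Iw*Io        df/dIs = Rw*Io - Iw*Ro
                # df/dRo = Rw*Rs - Iw*Is        df/dIo = Rw*Is + Iw*Rs
                rw, iw = params["rel_re"][r], params["rel_im"][r]
                if direction == "object":
                    rs, is_ = params["ent_re"][h], params["ent_im"][h]
                    ro, io = params["ent_re"][cands], params["ent_im"][cands]
                    grads["rel_re"][r] += df @ (ro * rs + io * is_)
                    grads["rel_im"][r] += df @ (io * rs - ro * is_)
                    grads["ent_re"][h] += df @ (ro * rw + io * iw)
                    grads["ent_im"][h] += df @ (io * rw - ro * iw)
                    np.add.at(grads["ent_re"], cands,
                              df[:, None] * (rw * rs - iw * is_)[None, :])
                    np.add.at(grads["ent_im"], cands,
                              df[:, None] * (rw * is_ + iw * rs)[None, :])
                else:
                    ro, io = params["ent_re"][t], params["ent_im"][t]
                    rs, is_ = params["ent_re"][cands], params["ent_im"][cands]
                    grads["rel_re"][r] += df @ (rs * ro + is_ * io)
                    grads["rel_im"][r] += df @ (rs * io - is_ * ro)
                    grads["ent_re"][t] += df @ (rs * rw - is_ * iw)
                    grads["ent_im"][t] += df @ (is_ * rw + rs * iw)
                    np.add.at(grads["ent_re"], cands,
                              df[:, None] * (rw * ro + iw * io)[None, :])
                    np.add.at(grads["ent_im"], cands,
                              df[:, None] * (rw * io - iw * ro)[None, :])
        for k in params:
            grads[k] += 2.0 * lam * params[k]
            epoch_loss += lam * np.sum(params[k] ** 2)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); try a smaller learning rate"
            )
        history.append(float(epoch_loss))
        for k in params:
            accum[k] += grads[k] ** 2
            params[k] = params[k] - lr * grads[k] / (np.sqrt(accum[k]) + eps)

    return ComplExModel(graph.entities, graph.relations, **params), history


def write_triples(graph: KnowledgeGraph, path) -> None:
    """Serialize observed triples as 3-column TSV (head, relation, tail)."""
    with open(path, "w") as fh:
        for h, r, t in graph.triples:
            fh.write(f"{graph.entities[h]}\t{graph.relations[r]}\t{graph.entities[t]}\n")


def save_model(model: ComplExModel, path) -> None:
    """Checkpoint a model as JSON: vocabularies plus real/imaginary parts."""
    import json

    payload = {
        "entities": model.entities,
        "relations": model.relations,
        "ent_re": model.ent_re.tolist(),
        "ent_im": model.ent_im.tolist(),
        "rel_re": model.rel_re.tolist(),
        "rel_im": model.rel_im.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> ComplExModel:
    """Load a checkpoint written by :func:`save_model`."""
    import json

    with open(path) as fh:
        d = json.load(fh)
    return ComplExModel(
        d["entities"], d["relations"],
        np.asarray(d["ent_re"]), np.asarray(d["ent_im"]),
        np.asarray(d["rel_re"]), np.asarray(d["rel_im"]),
    )


def train_garg(graph_or_subjects, **kwargs) -> ComplExModel:
    """Functional wrapper: train embeddings on a graph or a subject list."""
    if isinstance(graph_or_subjects, KnowledgeGraph):
        graph = graph_or_subjects
        cfg = dict(dim=50, n_negatives=10, lam=1e-3, epochs=300, lr=1e-2, seed=0)
        cfg.update(kwargs)
        model, _ = _train(graph, **cfg)
        return model
    emb = GargEmbedder(**kwargs).fit(graph_or_subjects)
    return emb.model_
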