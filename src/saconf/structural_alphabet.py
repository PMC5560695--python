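"""Structural-alphabet encoding of Calpha traces.

Each overlapping four-Calpha fragment (i, i+1, i+2, i+3) is described by
four rigid-motion-invariant geometry descriptors:

    d1 = |Ca(i)   - Ca(i+2)|
    d2 = |Ca(i)   - Ca(i+3)|
    d3 = |Ca(i+1) - Ca(i+3)|
    d4 = signed out-of-plane position of Ca(i+3) relative to the plane
         of the first three Calpha (sign carries chirality: it flips
         under mirror reflection)

A hidden Markov model with Gaussian emissions over these descriptors —
a structural alphabet — assigns each fragment to one of K structural
letters (27 by default, labelled [a, A-Z]). The letter of fragment i is
assigned to residue i+2, so a chain of p residues yields p-3 letters at
residue positions 3..p-1. Letters are grouped into three secondary-
structure categories: by convention {a, A, V, W} are helix-specific,
{L, M, N, T, X} strand-specific, and the remaining 18 letters encode
loop conformations.

Decoding is maximum-a-posteriori Viterbi in log domain; missing or
geometrically degenerate fragments split a chain into independently
decoded runs. Training is Baum-Welch EM (delegated to hmmlearn) with
k-means initialization and a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from hmmlearn.hmm import GaussianHMM

from . import synthetic

DEFAULT_LABELS = "a" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ"  # 27 letters
DEFAULT_HELIX = set("aAVW")
DEFAULT_STRAND = set("LMNTX")

MISSING = "?"

#: triangle area (A^2) below which the first three Calpha of a fragment
#: are treated as collinear and d4 is undefined
COLLINEAR_TOL = 1e-6

HELIX = "HELIX"
STRAND = "STRAND"
LOOP = "LOOP"


class TooShortChainError(ValueError):
    """Chain has fewer than four Calpha coordinates."""


def compute_descriptors(ca_coords: np.ndarray) -> np.ndarray:
    """Four-Calpha fragment descriptors for one chain.

    Parameters
    ----------
    ca_coords : (p, 3) array
        Ordered Calpha coordinates in Angstrom. Rows may contain NaN for
        residues whose Calpha is absent.

    Returns
    -------
    (p-3, 4) array
        One descriptor row per fragment; rows containing any absent atom
        are all-NaN (missing). Fragments whose first three atoms are
        collinear get NaN in the d4 column only.
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("ca_coords must be an (p, 3) array")
    p = len(coords)
    if p < 4:
        raise TooShortChainError(f"need >= 4 Calpha coordinates, got {p}")
    a, b, c, d = coords[:-3], coords[1:-2], coords[2:-1], coords[3:]
    out = np.empty((p - 3, 4))
    out[:, 0] = np.linalg.norm(c - a, axis=1)
    out[:, 1] = np.linalg.norm(d - a, axis=1)
    out[:, 2] = np.linalg.norm(d - b, axis=1)
    normal = np.cross(b - a, c - a)
    area = 0.5 * np.linalg.norm(normal, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = normal / np.linalg.norm(normal, axis=1, keepdims=True)
        out[:, 3] = np.einsum("ij,ij->i", d - a, unit)
    out[area < COLLINEAR_TOL, 3] = np.nan
    window_missing = np.isnan(coords).any(axis=1)
    frag_missing = (window_missing[:-3] | window_missing[1:-2]
                    | window_missing[2:-1] | window_missing[3:])
    out[frag_missing] = np.nan
    return out


@dataclass
class AlphabetModel:
    """A K-state Gaussian-emission HMM over fragment descriptors."""

    labels: str
    initial_probs: np.ndarray       # (K,)
    transitions: np.ndarray         # (K, K) row-stochastic
    means: np.ndarray               # (K, 4)
    covariances: np.ndarray         # (K, 4, 4)
    ss_map: dict[str, str]          # letter -> HELIX | STRAND | LOOP
    provenance: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        if len(set(self.labels)) != self.K:
            raise ValueError("labels must be distinct")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.initial_probs.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probabilities must sum to 1")
        for k in range(self.K):
            cov = self.covariances[k]
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"covariance {k} not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance {k} not positive-definite")
        missing = [l for l in self.labels if l not in self.ss_map]
        if missing:
            raise ValueError(f"ss_map lacks letters {missing}")

    def ss_category(self, letter: str) -> str:
        if letter not in self.ss_map:
            raise KeyError(f"unknown structural letter {letter!r}")
        return self.ss_map[letter]

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "labels": self.labels,
            "initial_probs": self.initial_probs.tolist(),
            "transitions": self.transitions.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "ss_map": self.ss_map,
            "provenance": self.provenance,
        }
        return json.dumps(doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "AlphabetModel":
        doc = json.loads(text)
        model = cls(
            labels=doc["labels"],
            initial_probs=np.array(doc["initial_probs"]),
            transitions=np.array(doc["transitions"]),
            means=np.array(doc["means"]),
            covariances=np.array(doc["covariances"]),
            ss_map=dict(doc["ss_map"]),
            provenance=doc.get("provenance", {}),
        )
        model.validate()
        return model

    @classmethod
    def load(cls, path: str | Path) -> "AlphabetModel":
        return cls.from_json(Path(path).read_text())


_default_model_cache: AlphabetModel | None = None


def default_model() -> AlphabetModel:
    """The bundled 27-letter alphabet trained on the pinned synthetic corpus."""
    global _default_model_cache
    if _default_model_cache is None:
        text = resources.files("saconf").joinpath("data/default_model.json").read_text()
        _default_model_cache = AlphabetModel.from_json(text)
    return _default_model_cache


def ss_category(letter: str, model: AlphabetModel) -> str:
    """Secondary-structure category (HELIX/STRAND/LOOP) of one letter."""
    return model.ss_category(letter)


def _state_log_likelihoods(model: AlphabetModel, X: np.ndarray) -> np.ndarray:
    """(n, K) log emission densities."""
    n = len(X)
    out = np.empty((n, model.K))
    for k in range(model.K):
        cov = model.covariances[k]
        factor = cho_factor(cov, lower=True)
        diff = X - model.means[k]
        solved = cho_solve(factor, diff.T).T
        maha = np.einsum("ij,ij->i", diff, solved)
        logdet = 2.0 * np.log(np.diag(factor[0])).sum()
        out[:, k] = -0.5 * (maha + logdet + X.shape[1] * np.log(2.0 * np.pi))
    return out


def viterbi_path(model: AlphabetModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Most probable state path for one contiguous descriptor run.

    Returns (states, joint log-probability). Ties are broken toward the
    lower state index for determinism.
    """
    logB = _state_log_likelihoods(model, X)
    if not np.isfinite(logB).any(axis=1).all():
        pos = int(np.flatnonzero(~np.isfinite(logB).any(axis=1))[0])
        raise FloatingPointError(f"zero emission density for all states at position {pos}")
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.initial_probs)
        log_T = np.log(model.transitions)
    n, K = logB.shape
    delta = log_pi + logB[0]
    back = np.zeros((n, K), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + log_T          # (from, to)
        back[t] = np.argmax(scores, axis=0)      # argmax takes lowest index on ties
        delta = scores[back[t], np.arange(K)] + logB[t]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states, float(delta[states[-1]])


def viterbi_encode(descriptors: np.ndarray, model: AlphabetModel) -> str:
    """Encode one chain's descriptors into a structural-letter string.

    Missing/degenerate descriptor rows become the missing symbol ``?``
    and split the series into runs decoded independently from the
    model's initial distribution (no information bridges a gap).
    """
    desc = np.asarray(descriptors, dtype=float)
    letters = [MISSING] * len(desc)
    usable = ~np.isnan(desc).any(axis=1)
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        return "".join(letters)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    for run in runs:
        states, _ = viterbi_path(model, desc[run])
        for pos, s in zip(run, states):
            letters[pos] = model.labels[s]
    return "".join(letters)


def encode_chain(ca_coords: np.ndarray, model: AlphabetModel | None = None) -> str:
    """Convenience: descriptors + Viterbi in one call."""
    if model is None:
        model = default_model()
    return viterbi_encode(compute_descriptors(ca_coords), model)


# ---------------------------------------------------------------------
# training

def reference_descriptors() -> dict[str, np.ndarray]:
    """Descriptor vectors of ideal helix and strand geometry.

    The strand alternates between two pleat phases, so it has two
    reference descriptors (mirror pair in d4).
    """
    helix = compute_descriptors(synthetic._helix_points(8))[2]
    strand0 = compute_descriptors(synthetic._strand_points(8, phase=0))[2]
    strand1 = compute_descriptors(synthetic._strand_points(8, phase=1))[2]
    return {"helix": helix, "strand_even": strand0, "strand_odd": strand1}


def assign_ss_map(labels: str, means: np.ndarray,
                  helix_tol: float = 1.0, strand_tol: float = 1.5) -> dict[str, str]:
    """Label states helix/strand/loop by descriptor-space distance to
    ideal geometry; everything beyond both tolerances is loop."""
    refs = reference_descriptors()
    out = {}
    for letter, mean in zip(labels, means):
        d_h = np.linalg.norm(mean - refs["helix"])
        d_s = min(np.linalg.norm(mean - refs["strand_even"]),
                  np.linalg.norm(mean - refs["strand_odd"]))
        if d_h < helix_tol and d_h <= d_s:
            out[letter] = HELIX
        elif d_s < strand_tol:
            out[letter] = STRAND
        else:
            out[letter] = LOOP
    return out


def _runs_from_sets(descriptor_sets: list[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    """Concatenate contiguous non-missing runs for hmmlearn fitting."""
    runs = []
    for desc in descriptor_sets:
        desc = np.asarray(desc, dtype=float)
        usable = ~np.isnan(desc).any(axis=1)
        idx = np.flatnonzero(usable)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            if len(run) >= 2:
                runs.append(desc[run])
    X = np.concatenate(runs, axis=0)
    lengths = [len(r) for r in runs]
    return X, lengths


def train_alphabet(descriptor_sets: list[np.ndarray], K: int = 27, seed: int = 0,
                   max_iter: int = 200, tol: float = 1e-4,
                   labels: str | None = None) -> tuple[AlphabetModel, dict]:
    """Fit a K-state Gaussian HMM alphabet by Baum-Welch EM.

    Initialization is k-means on the pooled descriptors with the given
    seed; covariances are regularized by a small diagonal floor
    (1e-4 A^2). Returns the model and a fitting log containing the
    per-iteration total log-likelihood (non-decreasing) and convergence
    status. Secondary-structure categories are assigned afterwards from
    the state means (``assign_ss_map``).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X, lengths = _runs_from_sets(descriptor_sets)
    if K >= 2 and len(X) < 50 * K:
        raise ValueError(f"need >= {50 * K} descriptors to fit K={K}, got {len(X)}")
    if labels is None:
        if K > len(DEFAULT_LABELS):
            raise ValueError("provide labels explicitly for K > 27")
        labels = DEFAULT_LABELS[:K]
    if K == 1:
        mean = X.mean(axis=0)
        cov = np.cov(X.T, bias=True) + 1e-4 * np.eye(4)
        model = AlphabetModel(labels=labels, initial_probs=np.ones(1),
                              transitions=np.ones((1, 1)), means=mean[None],
                              covariances=cov[None],
                              ss_map=assign_ss_map(labels, mean[None]),
                              provenance={"K": 1, "seed": seed})
        return model, {"log_likelihood": [], "converged": True}
    hmm = GaussianHMM(n_components=K, covariance_type="full",
                      n_iter=max_iter, tol=tol, min_covar=1e-4,
                      random_state=seed, init_params="stmc")
    hmm.fit(X, lengths)
    covs = hmm.covars_ + 1e-6 * np.eye(4)  # guard strict positive-definiteness
    model = AlphabetModel(
        labels=labels,
        initial_probs=hmm.startprob_.copy(),
        transitions=hmm.transmat_.copy(),
        means=hmm.means_.copy(),
        covariances=covs,
        ss_map=assign_ss_map(labels, hmm.means_),
        provenance={"K": K, "seed": seed, "n_descriptors": int(len(X)),
                    "n_runs": len(lengths), "max_iter": max_iter, "tol": tol},
    )
    log = {"log_likelihood": list(hmm.monitor_.history),
           "converged": bool(hmm.monitor_.converged)}
    if not hmm.monitor_.converged:
        log["warning"] = f"EM did not converge within {max_iter} iterations"
    model.validate()
    return model, log


def train_default_model(seed: int = 2024) -> AlphabetModel:
    """Train the bundled 27-letter model on the pinned synthetic corpus.

    After EM, states are relabelled so the canonical category letters
    hold: the states that actually decode ideal helix/strand geometry —
    completed by descriptor-space ranking to exactly 4 helix and 5
    strand states — receive the letters {a, A, V, W} and {L, M, N, T, X}
    respectively; the remaining 18 states take the remaining letters and
    map to loop.
    """
    corpus = synthetic.training_corpus(seed=seed)
    descriptor_sets = [compute_descriptors(c) for c in corpus]
    model, log = train_alphabet(descriptor_sets, K=27, seed=seed)

    refs = reference_descriptors()
    # states observed on perfectly ideal geometry
    helix_states = set()
    strand_states = set()
    ideal_helix = compute_descriptors(synthetic._helix_points(30))
    ideal_strand = compute_descriptors(synthetic._strand_points(30))
    tmp = AlphabetModel(labels=model.labels, initial_probs=model.initial_probs,
                        transitions=model.transitions, means=model.means,
                        covariances=model.covariances,
                        ss_map={l: LOOP for l in model.labels})
    helix_states.update(viterbi_path(tmp, ideal_helix)[0].tolist())
    strand_states.update(viterbi_path(tmp, ideal_strand)[0].tolist())
    strand_states -= helix_states

    d_helix = np.linalg.norm(model.means - refs["helix"], axis=1)
    d_strand = np.minimum(
        np.linalg.norm(model.means - refs["strand_even"], axis=1),
        np.linalg.norm(model.means - refs["strand_odd"], axis=1))
    for s in sorted(np.argsort(d_helix).tolist(), key=lambda s: d_helix[s]):
        if len(helix_states) >= 4:
            break
        if s not in helix_states and s not in strand_states:
            helix_states.add(s)
    for s in sorted(np.argsort(d_strand).tolist(), key=lambda s: d_strand[s]):
        if len(strand_states) >= 5:
            break
        if s not in helix_states and s not in strand_states:
            strand_states.add(s)
    helix_list = sorted(helix_states)[:4]
    strand_list = sorted(strand_states - set(helix_list))[:5]
    loop_list = [s for s in range(27) if s not in helix_list and s not in strand_list]

    # permutation: state -> letter
    letter_of_state = {}
    for s, letter in zip(helix_list, "aAVW"):
        letter_of_state[s] = letter
    for s, letter in zip(strand_list, "LMNTX"):
        letter_of_state[s] = letter
    loop_letters = [l for l in DEFAULT_LABELS if l not in set("aAVWLMNTX")]
    for s, letter in zip(loop_list, loop_letters):
        letter_of_state[s] = letter
    order = sorted(range(27), key=lambda s: DEFAULT_LABELS.index(letter_of_state[s]))
    perm = np.array(order)
    ss_map = {DEFAULT_LABELS[i]: (HELIX if DEFAULT_LABELS[i] in DEFAULT_HELIX
                                  else STRAND if DEFAULT_LABELS[i] in DEFAULT_STRAND
                                  else LOOP)
              for i in range(27)}
    relabelled = AlphabetModel(
        labels=DEFAULT_LABELS,
        initial_probs=model.initial_probs[perm],
        transitions=model.transitions[np.ix_(perm, perm)],
        means=model.means[perm],
        covariances=model.covariances[perm],
        ss_map=ss_map,
        provenance={**model.provenance, "corpus": "synthetic.training_corpus",
                    "corpus_seed": seed, "relabelled": True,
                    "converged": log["converged"]},
    )
    relabelled.validate()
    return relabelled
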