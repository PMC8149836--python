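"""Synthetic targets, natives, decoy pools, noisy predicted maps and scores.

The generator emulates the data a CASP-style EMA pipeline consumes without
any downloads: a compact self-avoiding Cα random walk serves as the native
structure, decoys are the native perturbed by chain-correlated Gaussian
displacement of graded magnitude (so pool quality spans the GDT-TS range),
the predicted distance map is the native Cβ map plus symmetric Gaussian
noise, and external quality-score columns are sampled to correlate with
true quality at a chosen level. Target difficulty categories are encoded
through the map-noise level. Nothing here claims biological realism; see
the methods note for what these pools do and do not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .structio import (
    Contact,
    ContactList,
    DataError,
    DistanceMap,
    ProteinModel,
    TargetRecord,
    classify_separation,
)

logger = logging.getLogger(__name__)

CA_SPACING = 3.8       # Å between consecutive Cα
MIN_NONADJ_DIST = 4.0  # Å self-avoidance for non-adjacent residues
CB_OFFSET = 1.5        # Å Cβ displacement off Cα
COMPACTNESS_BIAS = 0.9
MAX_RETRIES = 10_000
SMOOTH_WINDOW = 5      # residues; moving average applied to decoy noise

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_SIGMAS = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class SynthSpec:
    """Study conditions for one synthetic benchmark."""

    n_targets: int = 10
    L: int = 60
    decoys_per_target: int = 100
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    taus: tuple[float, ...] = (0.5, 3.0)  # easy / hard map noise (Å)
    rho: float = 0.6                      # external-score correlation
    partial_fraction: float = 0.1         # decoys with a dropped terminus
    seed: int = 0
    external_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_targets, self.L, self.decoys_per_target) < 1:
            raise DataError("all counts must be >= 1")
        if any(s < 0 for s in self.sigmas) or any(t < 0 for t in self.taus):
            raise DataError("noise levels must be >= 0")
        if not (0.0 <= self.rho <= 1.0):
            raise DataError("rho must lie in [0, 1]")


def _cb_positions(ca: np.ndarray) -> np.ndarray:
    """Place Cβ 1.5 Å off each Cα along a deterministic local-frame direction."""
    n = len(ca)
    cb = np.empty_like(ca)
    for i in range(n):
        if 0 < i < n - 1:
            v1 = ca[i] - ca[i - 1]
            v2 = ca[i] - ca[i + 1]
            direction = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        elif i == 0 and n > 1:
            direction = np.cross(ca[0] - ca[1], [0.0, 0.0, 1.0])
        elif i == n - 1 and n > 1:
            direction = np.cross(ca[-1] - ca[-2], [0.0, 0.0, 1.0])
        else:
            direction = np.array([1.0, 0.0, 0.0])
        norm = np.linalg.norm(direction)
        if norm < 1e-9:  # collinear fallback
            direction = np.cross(ca[i] - ca[i - 1], [1.0, 0.0, 0.0])
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                direction, norm = np.array([0.0, 1.0, 0.0]), 1.0
        cb[i] = ca[i] + CB_OFFSET * direction / norm
    return cb


def generate_native(L: int, seed: int, target_id: str = "synthetic") -> ProteinModel:
    """Compact self-avoiding Cα walk with derived Cβ positions.

    Consecutive Cα are 3.8 Å apart and non-adjacent pairs stay >= 4.0 Å; a
    bias toward the current centroid keeps the chain compact enough to form
    long-range contacts.
    """
    if L < 5:
        raise DataError("native generation requires L >= 5")
    rng = np.random.default_rng(seed)
    ca = np.zeros((L, 3))
    ca[1] = [CA_SPACING, 0.0, 0.0]
    for i in range(2, L):
        centroid = ca[:i].mean(axis=0)
        placed = False
        for _ in range(MAX_RETRIES):
            g = rng.normal(size=3)
            to_centroid = centroid - ca[i - 1]
            norm = np.linalg.norm(to_centroid)
            if norm > 1e-9:
                g = g + COMPACTNESS_BIAS * to_centroid / norm
            g /= np.linalg.norm(g)
            candidate = ca[i - 1] + CA_SPACING * g
            if cdist(candidate[None], ca[:i - 1]).min() >= MIN_NONADJ_DIST:
                ca[i] = candidate
                placed = True
                break
        if not placed:
            raise DataError(
                f"could not place residue {i + 1} after {MAX_RETRIES} retries; "
                "try a larger box (smaller compactness bias)"
            )
    return ProteinModel(
        target_id=target_id,
        model_id="native",
        residue_ids=np.arange(1, L + 1),
        ca_coords=ca,
        cb_coords=_cb_positions(ca),
        length=L,
    )


def random_sequence(L: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=L))


def _smoothed_noise(rng: np.random.Generator, L: int, sigma: float) -> np.ndarray:
    """Chain-correlated displacement field with per-atom sd ``sigma``.

    IID Gaussian noise is convolved with a moving average along the chain
    (window 5) and rescaled; the correlation keeps local geometry intact so
    quality degrades gradually instead of collapsing.
    """
    raw = rng.normal(size=(L, 3))
    kernel = np.ones(SMOOTH_WINDOW) / SMOOTH_WINDOW
    smooth = np.apply_along_axis(
        lambda col: np.convolve(np.pad(col, SMOOTH_WINDOW // 2, mode="edge"),
                                kernel, mode="valid"), 0, raw)
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros((L, 3))
    return smooth * (sigma / sd)


def generate_decoys(native: ProteinModel, sigmas, n_per_sigma: int, seed: int,
                    partial_fraction: float = 0.0) -> list[ProteinModel]:
    """Decoy pool of graded quality around a native structure.

    Each decoy displaces the native Cα/Cβ by a smoothed Gaussian field with
    per-atom sd σ; σ = 0 reproduces the native exactly. A fraction of
    decoys optionally loses a terminal segment to create partial models.
    """
    if any(s < 0 for s in sigmas):
        raise DataError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    L = native.length
    decoys = []
    idx = 0
    for sigma in sigmas:
        for _ in range(n_per_sigma):
            noise = _smoothed_noise(rng, L, sigma) if sigma > 0 else np.zeros((L, 3))
            ca = native.ca_coords + noise
            cb = native.cb_coords + noise
            rid = np.arange(1, L + 1)
            if partial_fraction > 0 and rng.random() < partial_fraction:
                cut = int(rng.integers(L // 10, L // 4 + 1))
                if rng.random() < 0.5:
                    keep = slice(cut, L)
                else:
                    keep = slice(0, L - cut)
                rid, ca, cb = rid[keep], ca[keep], cb[keep]
            decoys.append(ProteinModel(
                target_id=native.target_id,
                model_id=f"decoy_{idx:04d}",
                residue_ids=rid,
                ca_coords=ca,
                cb_coords=cb,
                length=L,
            ))
            idx += 1
    return decoys


def generate_pdm(native: ProteinModel, tau: float, seed: int) -> DistanceMap:
    """Predicted distance map: native Cβ map plus symmetric noise (sd τ)."""
    if tau < 0:
        raise DataError("tau must be >= 0")
    rng = np.random.default_rng(seed)
    values = squareform(pdist(native.cb_coords))
    if tau > 0:
        noise = rng.normal(0.0, tau, values.shape)
        upper = np.triu(noise, k=1)
        values = values + upper + upper.T
    values = np.clip(values, 0.0, None)
    np.fill_diagonal(values, 0.0)
    return DistanceMap.full(values)


def contacts_from_pdm(pdm: DistanceMap, threshold: float = 8.0,
                      sharpness: float = 1.0) -> ContactList:
    """Threshold a predicted map into an RR-style contact list.

    Contact probability is a logistic function of the margin below the
    threshold, so confident (short-distance) contacts score near 1.
    """
    L = pdm.size
    contacts = []
    iu, ju = np.triu_indices(L, k=6)
    for i, j in zip(iu, ju):
        d = pdm.values[i, j]
        if d < threshold and pdm.observed[i, j]:
            rc = classify_separation(j - i)
            p = 1.0 / (1.0 + np.exp(-sharpness * (threshold - d)))
            contacts.append(Contact(int(i) + 1, int(j) + 1, float(p), rc))
    return ContactList(contacts)


def surrogate_externals(true_scores: np.ndarray, columns, rho: float,
                        seed: int) -> pd.DataFrame:
    """Synthetic external-score columns correlated with true quality.

    Each column is ρ·standardized(truth) + √(1−ρ²)·noise, min-max rescaled
    to [0, 1]; it stands in for a third-party single-model score of chosen
    informativeness.
    """
    if not (0.0 <= rho <= 1.0):
        raise DataError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.asarray(true_scores, dtype=float)
    sd = t.std()
    z = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
    out = {}
    for col in columns:
        raw = rho * z + np.sqrt(1.0 - rho ** 2) * rng.normal(size=len(t))
        span = raw.max() - raw.min()
        out[col] = (raw - raw.min()) / span if span > 0 else np.full(len(t), 0.5)
    return pd.DataFrame(out)


@dataclass
class SynthTarget:
    """One generated target with everything the pipeline consumes."""

    target: TargetRecord
    native: ProteinModel
    decoys: list[ProteinModel]
    pdm: DistanceMap
    contacts: ContactList
    true_scores: pd.DataFrame  # target_id, model_id, label (GDT-TS)
    externals: pd.DataFrame | None
    category: str
    tau: float


def generate_target_pool(spec: SynthSpec, index: int, seed: int) -> SynthTarget:
    """Generate target ``index`` of a benchmark: native, decoys, PDM, scores."""
    from .scoring import gdt_ts

    ss = np.random.SeedSequence([seed, index])
    seeds = [int(s) for s in ss.generate_state(5)]
    target_id = f"SYN{index:04d}"
    native = generate_native(spec.L, seeds[0] % 2**31, target_id=target_id)
    target = TargetRecord(target_id=target_id,
                          sequence=random_sequence(spec.L, seeds[1] % 2**31))
    n_per_sigma = int(np.ceil(spec.decoys_per_target / len(spec.sigmas)))
    decoys = generate_decoys(
        native, spec.sigmas, n_per_sigma, seeds[2] % 2**31,
        partial_fraction=spec.partial_fraction,
    )[: spec.decoys_per_target]
    tau = spec.taus[index % len(spec.taus)]
    category = "TBM-easy" if tau <= min(spec.taus) else "FM"
    pdm = generate_pdm(native, tau, seeds[3] % 2**31)
    contacts = contacts_from_pdm(pdm)
    labels = [gdt_ts(d, native) for d in decoys]
    true_scores = pd.DataFrame({
        "target_id": target_id,
        "model_id": [d.model_id for d in decoys],
        "label": labels,
    })
    externals = None
    if spec.external_columns:
        externals = surrogate_externals(
            np.asarray(labels), spec.external_columns, spec.rho, seeds[4] % 2**31)
        externals.insert(0, "model_id", [d.model_id for d in decoys])
        externals.insert(0, "target_id", target_id)
    return SynthTarget(
        target=target, native=native, decoys=decoys, pdm=pdm,
        contacts=contacts, true_scores=true_scores, externals=externals,
        category=category, tau=tau,
    )


def make_benchmark(spec: SynthSpec, preset: str = "deep"):
    """End-to-end dataset: feature table, label table and category labels."""
    from .map_features import CONSENSUS_FEATURE, PRESETS, featurize_model
    from .scoring import pairwise_consensus

    from .map_features import DIST_FEATURES, compute_artifacts

    feature_rows, label_frames, categories = [], [], {}
    needs_consensus = CONSENSUS_FEATURE in PRESETS[preset]["internal"]
    needs_maps = bool(set(PRESETS[preset]["internal"])
                      & (set(DIST_FEATURES) | {"correlation_feature"}))
    for index in range(spec.n_targets):
        st = generate_target_pool(spec, index, spec.seed)
        categories[st.target.target_id] = st.category
        label_frames.append(st.true_scores)
        pdm_art = compute_artifacts(st.pdm) if needs_maps else None
        consensus = pairwise_consensus(st.decoys) if needs_consensus else None
        ext_rows = None
        if st.externals is not None:
            ext_rows = st.externals.set_index("model_id")
        for m_idx, decoy in enumerate(st.decoys):
            ext = None
            if ext_rows is not None:
                ext = {c: float(ext_rows.loc[decoy.model_id, c])
                       for c in spec.external_columns}
            fv = featurize_model(
                st.target, decoy, st.pdm, contacts=st.contacts,
                externals=ext, preset=preset,
                consensus=None if consensus is None else float(consensus[m_idx]),
                allow_missing_externals=True,
                pdm_artifacts=pdm_art,
            )
            feature_rows.append({"target_id": st.target.target_id,
                                 "model_id": decoy.model_id, **fv.values})
    features = pd.DataFrame(feature_rows)
    labels = pd.concat(label_frames, ignore_index=True)
    cats = pd.DataFrame({"target_id": list(categories),
                         "category": list(categories.values())})
    return features, labels, cats
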