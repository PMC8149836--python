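"""Distance-map and contact-match quality features.

One structural model is compared against the target's *predicted* distance
map (PDM): directly, via the Pearson correlation and RMSE of aligned map
entries and via contact recall/precision, and as images, by rendering both
maps to a common 128×128 8-bit grid and applying SSIM, PSNR, a DCT
perceptual hash, ORB keypoint matching and a Gabor (GIST-style) global
descriptor. Every feature is normalised so that similarity-type features
lie in [0, 1]; degenerate cases map to documented sentinels rather than
NaN so downstream training is total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as sp_fft
from skimage.feature import ORB
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .structio import (
    CONTACT_THRESHOLD,
    LONG_RANGE_MIN,
    MIN_SEPARATION,
    ContactList,
    DataError,
    DistanceMap,
    ProteinModel,
    TargetRecord,
    compute_distance_map,
    contacts_from_map,
)

logger = logging.getLogger(__name__)

DISTANCE_CAP = 16.0  # Å: distances beyond this carry no contact information
IMAGE_SIZE = 128
ORB_BUDGET = 500
ORB_RATIO = 0.75

#: canonical single-model distance-map feature names
DIST_FEATURES = (
    "dist_gist",
    "dist_precl2_long",
    "dist_precl2",
    "dist_ssim",
    "dist_psnr",
    "dist_recall_long",
    "dist_orb_num",
    "dist_pearson",
    "dist_phash",
    "dist_recall",
    "dist_rmse",
)
CONTACT_FEATURES = ("contact_short", "contact_medium", "contact_long")
CONSENSUS_FEATURE = "consensus_pairwise"

#: external single-model score columns (stand-ins for third-party programs)
EXTERNAL_SCORES9 = (
    "voronota", "sbrod", "opus_psp", "rf_cb_srs_od", "rwplus",
    "deepqa", "proq2", "proq3", "dope",
)
EXTERNAL_STRUCT6 = (
    "weighted_exposed", "total_surface", "solvent",
    "euclidean", "ss_penalty", "ss_sim",
)

# Feature subsets of the six EMA predictor presets. Each entry lists the
# internally computed features, the required external score columns, the
# cross-validation fold count K and whether stage-2 stacking is used.
PRESETS: dict[str, dict] = {
    "cluster": {
        "internal": CONTACT_FEATURES + (CONSENSUS_FEATURE,),
        "external": ("voronota", "sbrod", "opus_psp", "rf_cb_srs_od", "rwplus",
                     "deepqa", "proq2", "proq3", "dope") + EXTERNAL_STRUCT6,
        "k": 10,
        "two_stage": False,
    },
    "construct": {
        "internal": CONTACT_FEATURES + (CONSENSUS_FEATURE,),
        "external": ("voronota", "sbrod", "opus_psp", "rf_cb_srs_od", "rwplus",
                     "qmean", "modelevaluator", "feature_probability")
                    + EXTERNAL_STRUCT6,
        "k": 10,
        "two_stage": True,
    },
    "ai": {
        "internal": ("correlation_feature",) + CONTACT_FEATURES + (CONSENSUS_FEATURE,),
        "external": ("voronota", "sbrod", "opus_psp", "rf_cb_srs_od", "rwplus",
                     "deepqa", "dope") + EXTERNAL_STRUCT6,
        "k": 5,
        "two_stage": False,
    },
    "hybrid": {
        "internal": DIST_FEATURES + CONTACT_FEATURES + (CONSENSUS_FEATURE,),
        "external": EXTERNAL_SCORES9 + EXTERNAL_STRUCT6,
        "k": 10,
        "two_stage": True,
    },
    "deep": {
        "internal": DIST_FEATURES + CONTACT_FEATURES,
        "external": EXTERNAL_SCORES9 + EXTERNAL_STRUCT6,
        "k": 10,
        "two_stage": True,
    },
    "dist": {
        "internal": DIST_FEATURES,
        "external": ("voronota", "sbrod", "opus_psp", "rf_cb_srs_od",
                     "rwplus", "dope"),
        "k": 10,
        "two_stage": True,
    },
}


def preset_columns(preset: str, available_externals=None) -> list[str]:
    """Ordered feature columns of a preset.

    With ``available_externals`` given, external columns absent from it are
    dropped (logged), degrading the preset to its computable subset so the
    pipeline runs without third-party score files.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {', '.join(sorted(PRESETS))}"
        )
    p = PRESETS[preset]
    external = list(p["external"])
    if available_externals is not None:
        missing = [c for c in external if c not in available_externals]
        if missing:
            logger.info(
                "preset %r: external columns %s unavailable; degrading to the "
                "computable subset", preset, missing,
            )
        external = [c for c in external if c not in missing]
    return list(p["internal"]) + external


@dataclass
class MapImage:
    """A distance map rendered to a fixed 8-bit intensity grid."""

    pixels: np.ndarray  # uint8, (S, S)
    source_size: int


@dataclass
class FeatureVector:
    """Named per-model feature values."""

    target_id: str
    model_id: str
    values: dict[str, float]

    def as_array(self, columns) -> np.ndarray:
        return np.array([self.values[c] for c in columns], dtype=float)


# ---------------------------------------------------------------------------
# aligned map entries


def masked_pairs(pdm: DistanceMap, mdm: DistanceMap,
                 min_sep: int = MIN_SEPARATION) -> tuple[np.ndarray, np.ndarray]:
    """Aligned upper-triangle entries observed in both maps, |i-j| >= min_sep."""
    if pdm.size != mdm.size:
        raise DataError(f"map size mismatch: {pdm.size} vs {mdm.size}")
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    L = pdm.size
    ii, jj = np.triu_indices(L, k=min_sep)
    keep = pdm.observed[ii, jj] & mdm.observed[ii, jj]
    return pdm.values[ii[keep], jj[keep]], mdm.values[ii[keep], jj[keep]]


def dist_pearson(pdm: DistanceMap, mdm: DistanceMap) -> float:
    """Pearson correlation between aligned PDM and MDM entries (sentinel 0)."""
    a, b = masked_pairs(pdm, mdm)
    if len(a) < 3:
        logger.warning("dist_pearson: fewer than 3 aligned pairs; returning 0")
        return 0.0
    if a.std() == 0.0 or b.std() == 0.0:
        logger.warning("dist_pearson: zero variance; returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def dist_rmse(pdm: DistanceMap, mdm: DistanceMap, cap: float = DISTANCE_CAP) -> float:
    """RMSE between aligned map entries, clipped to the distance cap."""
    a, b = masked_pairs(pdm, mdm)
    if len(a) == 0:
        logger.warning("dist_rmse: no aligned pairs; returning cap %.1f", cap)
        return cap
    return float(min(np.sqrt(np.mean((a - b) ** 2)), cap))


# ---------------------------------------------------------------------------
# image rendering and similarity


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def map_to_image(dmap: DistanceMap, cap: float = DISTANCE_CAP,
                 size: int = IMAGE_SIZE) -> MapImage:
    """Render a distance map as an 8-bit image (short distances bright).

    Pixel intensity is ``round(255 * (1 - min(d, cap)/cap))``; unobserved
    cells render as 0. The full L×L grid is then resized bilinearly to the
    common ``size`` so image features are comparable across target lengths.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    d = np.minimum(dmap.values, cap)
    img = _round_half_up(255.0 * (1.0 - d / cap))
    img[~dmap.observed] = 0.0
    if dmap.size != size:
        img = resize(img, (size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    img = np.clip(_round_half_up(img), 0, 255).astype(np.uint8)
    return MapImage(pixels=img, source_size=dmap.size)


def _check_same_size(img_a: MapImage, img_b: MapImage) -> None:
    if img_a.pixels.shape != img_b.pixels.shape:
        raise DataError("images must have the same size")


def dist_ssim(img_a: MapImage, img_b: MapImage) -> float:
    """Mean SSIM (11×11 Gaussian window, σ=1.5), mapped to [0, 1]."""
    _check_same_size(img_a, img_b)
    s = structural_similarity(
        img_a.pixels, img_b.pixels, win_size=11, gaussian_weights=True,
        sigma=1.5, K1=0.01, K2=0.03, data_range=255,
        use_sample_covariance=False,
    )
    return float(np.clip((s + 1.0) / 2.0, 0.0, 1.0))


def dist_psnr(img_a: MapImage, img_b: MapImage, cap_db: float = 100.0) -> float:
    """PSNR in dB capped at 100 (identical images), scaled to [0, 1]."""
    _check_same_size(img_a, img_b)
    diff = img_a.pixels.astype(float) - img_b.pixels.astype(float)
    mse = float(np.mean(diff * diff))
    if mse < 255.0 ** 2 * 1e-10:
        return 1.0
    psnr = min(10.0 * np.log10(255.0 ** 2 / mse), cap_db)
    return float(psnr / cap_db)


def perceptual_hash(img: MapImage) -> np.ndarray:
    """64-bit DCT perceptual hash of an image.

    The image is resized to 32×32, 2-D DCT'd, and the 8×8 low-frequency
    block is kept; the DC term is dropped and the next coefficient appended
    so exactly 64 bits remain, thresholded at their median.
    """
    small = resize(img.pixels.astype(float), (32, 32), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    coeffs = sp_fft.dctn(small, type=2, norm="ortho")
    block = coeffs[:8, :8].ravel()
    bits_src = np.concatenate([block[1:], [coeffs[0, 8]]])
    return bits_src > np.median(bits_src)


def dist_phash(img_a: MapImage, img_b: MapImage) -> float:
    """1 − normalised Hamming distance between the two 64-bit hashes."""
    _check_same_size(img_a, img_b)
    ha, hb = perceptual_hash(img_a), perceptual_hash(img_b)
    return float(1.0 - np.count_nonzero(ha != hb) / 64.0)


def _orb_descriptors(pixels: np.ndarray) -> np.ndarray | None:
    orb = ORB(n_keypoints=ORB_BUDGET)
    try:
        orb.detect_and_extract(pixels.astype(float) / 255.0)
    except RuntimeError:  # featureless image: no keypoints found
        return None
    if orb.descriptors is None or len(orb.descriptors) == 0:
        return None
    return orb.descriptors


def dist_orb_num(img_a: MapImage, img_b: MapImage) -> float:
    """Fraction of the ORB keypoint budget matched between the images.

    Matching is brute-force Hamming with Lowe's ratio test (0.75); a best
    match at distance 0 is always accepted (so identical images match every
    detected keypoint).
    """
    _check_same_size(img_a, img_b)
    da = _orb_descriptors(img_a.pixels)
    db = _orb_descriptors(img_b.pixels)
    if da is None or db is None:
        return 0.0
    return _match_descriptors(da, db) / ORB_BUDGET


def _match_descriptors(da: np.ndarray, db: np.ndarray) -> int:
    """Count Lowe-ratio matches (a -> b) between binary descriptor sets."""
    pa = np.packbits(da.astype(bool), axis=1)
    pb = np.packbits(db.astype(bool), axis=1)
    dists = np.bitwise_count(pa[:, None, :] ^ pb[None, :, :]).sum(
        axis=2, dtype=np.int32)
    if dists.shape[1] == 1:
        return int(np.count_nonzero(dists[:, 0] == 0))
    two = np.partition(dists, 1, axis=1)[:, :2]
    best, second = two[:, 0], two[:, 1]
    accepted = (best == 0) | ((second > 0) & (best < ORB_RATIO * second))
    return int(np.count_nonzero(accepted))


@lru_cache(maxsize=4)
def _gabor_bank(shape: tuple[int, int]):
    """Precomputed frequency-domain Gabor bank (4 scales × 8 orientations)."""
    from skimage.filters import gabor_kernel

    kernels = [
        np.asarray(gabor_kernel(frequency, theta=theta))
        for frequency in (0.05, 0.1, 0.2, 0.4)
        for theta in np.arange(8) * np.pi / 8.0
    ]
    kmax = max(max(k.shape) for k in kernels)
    fshape = (shape[0] + kmax - 1, shape[1] + kmax - 1)
    ffts, offsets = [], []
    for k in kernels:
        ffts.append(sp_fft.fft2(k, fshape))
        offsets.append(((k.shape[0] - 1) // 2, (k.shape[1] - 1) // 2))
    return fshape, ffts, offsets


def gist_descriptor(img: MapImage, grid: int = 4) -> np.ndarray:
    """GIST-style descriptor: mean Gabor response magnitude on a 4×4 grid.

    4 scales × 8 orientations × 16 cells = 512 dimensions.
    """
    pixels = img.pixels.astype(float)
    h, w = pixels.shape
    fshape, ffts, offsets = _gabor_bank((h, w))
    img_fft = sp_fft.fft2(pixels, fshape)
    gh, gw = h // grid, w // grid
    feats = np.empty(len(ffts) * grid * grid)
    pos = 0
    for kf, (oy, ox) in zip(ffts, offsets):
        conv = sp_fft.ifft2(img_fft * kf)[oy:oy + h, ox:ox + w]
        mag = np.abs(conv)
        cells = mag[: gh * grid, : gw * grid].reshape(grid, gh, grid, gw)
        feats[pos:pos + grid * grid] = cells.mean(axis=(1, 3)).ravel()
        pos += grid * grid
    return feats


def dist_gist(img_a: MapImage, img_b: MapImage) -> float:
    """Cosine similarity of GIST descriptors, mapped to [0, 1]."""
    _check_same_size(img_a, img_b)
    ga, gb = gist_descriptor(img_a), gist_descriptor(img_b)
    na, nb = np.linalg.norm(ga), np.linalg.norm(gb)
    if na == 0.0 or nb == 0.0:
        return 1.0 if np.array_equal(img_a.pixels, img_b.pixels) else 0.5
    c = float(np.dot(ga, gb) / (na * nb))
    return float(np.clip((c + 1.0) / 2.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# per-map image artifacts (cacheable across a model pool)


@dataclass
class MapArtifacts:
    """Precomputed image-side quantities of one distance map.

    Computing these once per predicted map and reusing them across a whole
    model pool avoids repeating ORB detection and the Gabor bank on the
    same image hundreds of times.
    """

    image: MapImage
    phash: np.ndarray
    orb: np.ndarray | None
    gist: np.ndarray


def compute_artifacts(dmap: DistanceMap, cap: float = DISTANCE_CAP,
                      size: int = IMAGE_SIZE) -> MapArtifacts:
    img = map_to_image(dmap, cap=cap, size=size)
    return MapArtifacts(
        image=img,
        phash=perceptual_hash(img),
        orb=_orb_descriptors(img.pixels),
        gist=gist_descriptor(img),
    )


def _image_features(pa: MapArtifacts, ma: MapArtifacts) -> dict[str, float]:
    """All image-similarity features from two precomputed artifact sets."""
    out = {
        "dist_ssim": dist_ssim(pa.image, ma.image),
        "dist_psnr": dist_psnr(pa.image, ma.image),
        "dist_phash": float(1.0 - np.count_nonzero(pa.phash != ma.phash) / 64.0),
    }
    if pa.orb is None or ma.orb is None:
        out["dist_orb_num"] = 0.0
    else:
        out["dist_orb_num"] = _match_descriptors(pa.orb, ma.orb) / ORB_BUDGET
    na, nb = np.linalg.norm(pa.gist), np.linalg.norm(ma.gist)
    if na == 0.0 or nb == 0.0:
        out["dist_gist"] = (
            1.0 if np.array_equal(pa.image.pixels, ma.image.pixels) else 0.5
        )
    else:
        c = float(np.dot(pa.gist, ma.gist) / (na * nb))
        out["dist_gist"] = float(np.clip((c + 1.0) / 2.0, 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# contact-style map features


def dist_recall(pdm: DistanceMap, mdm: DistanceMap, long_only: bool = False,
                threshold: float = CONTACT_THRESHOLD) -> float:
    """Fraction of PDM contacts realised in the model's map.

    Predicted contacts are map entries under the 8 Å threshold (long range,
    or all pairs with separation >= 6). Pairs unobserved in the model's map
    (missing residues) are excluded from both numerator and denominator.
    """
    range_class = "long" if long_only else "all"
    predicted = contacts_from_map(pdm, threshold, range_class)
    usable = [(i, j) for (i, j) in predicted if mdm.observed[i - 1, j - 1]]
    if not usable:
        return 0.0
    realized = sum(1 for (i, j) in usable if mdm.values[i - 1, j - 1] < threshold)
    return realized / len(usable)


def dist_precl2(pdm: DistanceMap, mdm: DistanceMap, long_only: bool = False,
                threshold: float = CONTACT_THRESHOLD) -> float:
    """Precision of the top ⌈L/2⌉ predicted pairs ranked by PDM distance.

    Candidates are pairs observed in both maps with separation >= 24 (long)
    or >= 6 (all); ties in predicted distance break lexicographically on
    (i, j) for determinism.
    """
    if pdm.size != mdm.size:
        raise DataError(f"map size mismatch: {pdm.size} vs {mdm.size}")
    L = pdm.size
    min_sep = LONG_RANGE_MIN if long_only else MIN_SEPARATION
    ii, jj = np.triu_indices(L, k=min_sep)
    keep = pdm.observed[ii, jj] & mdm.observed[ii, jj]
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        logger.warning("dist_precl2: no candidate pairs; returning 0")
        return 0.0
    vals = pdm.values[ii, jj]
    order = np.lexsort((jj, ii, vals))
    top = order[: int(np.ceil(L / 2.0))]
    hits = np.count_nonzero(mdm.values[ii[top], jj[top]] < threshold)
    return hits / len(top)


def contact_match(contacts: ContactList, mdm: DistanceMap, range_class: str,
                  threshold: float = CONTACT_THRESHOLD) -> float:
    """Fraction of listed contacts of a class realised in the model's map.

    Pairs touching missing model residues are excluded from both numerator
    and denominator; 0 when nothing is listed.
    """
    pairs = [
        (c.i, c.j) for c in contacts.by_class(range_class)
        if c.j <= mdm.size and mdm.observed[c.i - 1, c.j - 1]
    ]
    if not pairs:
        return 0.0
    hits = sum(1 for (i, j) in pairs if mdm.values[i - 1, j - 1] < threshold)
    return hits / len(pairs)


# ---------------------------------------------------------------------------
# assembly


def featurize_model(target: TargetRecord, model: ProteinModel, pdm: DistanceMap,
                    contacts: ContactList | None = None,
                    externals: dict[str, float] | None = None,
                    preset: str = "deep",
                    consensus: float | None = None,
                    allow_missing_externals: bool = False,
                    pdm_artifacts: MapArtifacts | None = None) -> FeatureVector:
    """Assemble the feature vector of one model for a given preset.

    The model's distance map (MDM, Cβ scheme) is computed internally. The
    ``consensus_pairwise`` pool feature and any external score columns are
    supplied by the caller; a preset that requires a column not provided
    raises an error naming the missing columns, unless
    ``allow_missing_externals`` degrades the preset to its computable subset.
    """
    if model.target_id != target.target_id:
        raise DataError(
            f"model target_id {model.target_id!r} != target {target.target_id!r}"
        )
    externals = dict(externals or {})
    if consensus is not None:
        externals.setdefault(CONSENSUS_FEATURE, consensus)
    if allow_missing_externals:
        available = set(PRESETS[preset]["internal"]) | set(externals)
        columns = preset_columns(preset, available_externals=available)
    else:
        columns = preset_columns(preset)

    internal_needed = set(PRESETS[preset]["internal"])
    values: dict[str, float] = {}

    needs_maps = bool(internal_needed & (set(DIST_FEATURES) | {"correlation_feature"}))
    if needs_maps:
        if pdm.size != target.L:
            raise DataError(f"PDM size {pdm.size} != target length {target.L}")
        mdm = compute_distance_map(model, atom_scheme="cb")
        r = dist_pearson(pdm, mdm)
        values["dist_pearson"] = r
        values["correlation_feature"] = r  # identical definition, both names kept
        values["dist_rmse"] = dist_rmse(pdm, mdm)
        values["dist_recall"] = dist_recall(pdm, mdm, long_only=False)
        values["dist_recall_long"] = dist_recall(pdm, mdm, long_only=True)
        values["dist_precl2"] = dist_precl2(pdm, mdm, long_only=False)
        values["dist_precl2_long"] = dist_precl2(pdm, mdm, long_only=True)
        if pdm_artifacts is None:
            pdm_artifacts = compute_artifacts(pdm)
        values.update(_image_features(pdm_artifacts, compute_artifacts(mdm)))
    elif {"contact_short", "contact_medium", "contact_long"} & internal_needed:
        mdm = compute_distance_map(model, atom_scheme="cb")

    if {"contact_short", "contact_medium", "contact_long"} & internal_needed:
        if contacts is None:
            raise DataError(
                f"preset {preset!r} requires a contact list (contact_* features)"
            )
        values["contact_short"] = contact_match(contacts, mdm, "short")
        values["contact_medium"] = contact_match(contacts, mdm, "medium")
        values["contact_long"] = contact_match(contacts, mdm, "long")

    missing = [c for c in columns if c not in values and c not in externals]
    if missing:
        raise DataError(
            f"preset {preset!r} requires missing feature columns: {', '.join(missing)}"
        )
    for c in columns:
        if c not in values:
            values[c] = float(externals[c])
    return FeatureVector(
        target_id=target.target_id,
        model_id=model.model_id,
        values={c: values[c] for c in columns},
    )
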