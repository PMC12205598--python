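"""Per-cell frames, morphology features and 128-dimensional embeddings.

Each segmented instance yields a 64x64 frame centered on its centroid
(reflection-padded near borders), a set of standard region-property
morphology features, and a 128-d embedding.  Two embedding backends sit
behind one interface:

* :class:`DeterministicEmbedder` — handcrafted, seed-free features: 16
  intensity summaries, a 48-bin radial profile of the mean-subtracted frame,
  and a 64-bin histogram of centred/scaled intensities.  Fast, exactly
  reproducible, and structured so a constant intensity shift moves only the
  intensity-summary coordinates.
* :class:`ClassifierEmbedder` — a trainable protein classifier (multilayer
  perceptron, categorical cross-entropy) whose 128-unit penultimate hidden
  layer is read out as the embedding, mirroring the train-to-classify /
  embed-from-penultimate-layer strategy used on real screens.  Trained on
  wild-type-background frames only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import regionprops

FRAME_SIZE = 64
EMBED_DIM = 128

MORPHOLOGY_FEATURES = (
    "area",
    "convex_area",
    "equivalent_diameter",
    "perimeter",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "solidity",
    "orientation",
    "euler_number",
)


@dataclass
class CellRecord:
    """One segmented cell: identity, position, frames and morphology."""

    cell_id: str
    protein: str
    background: str
    replicate: int
    field: int
    center: tuple[int, int]
    frame: np.ndarray  # 64x64 patch from the normalized image
    raw_frame: np.ndarray | None = None  # 64x64 patch from the raw image
    morphology: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.shape != (FRAME_SIZE, FRAME_SIZE):
            raise ValueError(f"frame must be {FRAME_SIZE}x{FRAME_SIZE}")


def _padded_crop(image: np.ndarray, center: tuple[int, int], half: int) -> np.ndarray:
    padded = np.pad(image, half, mode="reflect")
    r, c = center
    return padded[r : r + 2 * half, c : c + 2 * half]


def extract_frames(
    image: np.ndarray,
    mask: np.ndarray,
    raw_image: np.ndarray | None = None,
    protein: str = "",
    background: str = "",
    replicate: int = 0,
    field_no: int = 0,
) -> list[CellRecord]:
    """One 64x64 frame per instance, centered on the rounded centroid.

    Frames within 32 px of a border are completed by reflection padding.
    ``image`` is normally the normalized field (used for embeddings);
    ``raw_image`` optionally supplies raw-intensity frames for abundance.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    half = FRAME_SIZE // 2
    records: list[CellRecord] = []
    for prop in regionprops(np.asarray(mask)):
        r, c = (int(round(x)) for x in prop.centroid)
        r = min(max(r, 0), image.shape[0] - 1)
        c = min(max(c, 0), image.shape[1] - 1)
        frame = _padded_crop(image, (r, c), half)
        raw_frame = _padded_crop(np.asarray(raw_image, dtype=float), (r, c), half) \
            if raw_image is not None else None
        records.append(
            CellRecord(
                cell_id=f"{protein}_{background}_r{replicate}_f{field_no}_c{prop.label}",
                protein=protein,
                background=background,
                replicate=replicate,
                field=field_no,
                center=(r, c),
                frame=frame,
                raw_frame=raw_frame,
                morphology=morphology(prop.image),
            )
        )
    return records


def morphology(stencil: np.ndarray) -> dict[str, float]:
    """Standard region properties of a single cell stencil.

    area; convex area (area of the convex hull image); equivalent diameter
    (diameter of the circle with the same area); perimeter; eccentricity of
    the equivalent ellipse; major/minor axis lengths; solidity
    (area / convex area); orientation; Euler number (regions minus holes).
    """
    stencil = np.asarray(stencil).astype(bool)
    if not stencil.any():
        raise ValueError("empty stencil has no morphology")
    props = regionprops(stencil.astype(np.uint8))
    if len(props) != 1:
        # regionprops on a binary image yields a single region for any
        # nonempty stencil; guard anyway
        raise ValueError("stencil must contain exactly one labeled region")
    p = props[0]
    return {
        "area": float(p.area),
        "convex_area": float(p.area_convex),
        "equivalent_diameter": float(p.equivalent_diameter_area),
        "perimeter": float(p.perimeter),
        "eccentricity": float(p.eccentricity),
        "major_axis_length": float(p.axis_major_length),
        "minor_axis_length": float(p.axis_minor_length),
        "solidity": float(p.solidity),
        "orientation": float(p.orientation),
        "euler_number": float(p.euler_number),
    }


# ---------------------------------------------------------------------------
# deterministic embedding backend
# ---------------------------------------------------------------------------

_N_SUMMARY = 16
_N_RADIAL = 48
_N_HIST = 64
INTENSITY_SUMMARY_SLICE = slice(0, _N_SUMMARY)


def _radial_bin_index() -> np.ndarray:
    half = FRAME_SIZE // 2
    rr, cc = np.mgrid[0:FRAME_SIZE, 0:FRAME_SIZE].astype(float)
    r = np.hypot(rr - (half - 0.5), cc - (half - 0.5))
    rmax = np.hypot(half, half) + 1e-9
    return np.minimum((r / rmax * _N_RADIAL).astype(int), _N_RADIAL - 1)


_RADIAL_IDX = _radial_bin_index()
_RADIAL_COUNTS = np.bincount(_RADIAL_IDX.ravel(), minlength=_N_RADIAL).astype(float)


class DeterministicEmbedder:
    """Seed-free handcrafted 128-d embedding.

    Coordinates 0–15 are intensity summaries (sensitive to overall
    brightness); 16–63 are the mean radial profile of the mean-subtracted
    frame (localization pattern, invariant to constant shifts); 64–127 are a
    histogram of centred, scale-normalized intensities (texture/contrast
    shape, invariant to constant shifts).
    """

    dim = EMBED_DIM

    def embed(self, frames: list[np.ndarray] | np.ndarray) -> np.ndarray:
        frames = [np.asarray(f, dtype=float) for f in frames]
        out = np.empty((len(frames), EMBED_DIM))
        for i, f in enumerate(frames):
            if f.shape != (FRAME_SIZE, FRAME_SIZE):
                raise ValueError(f"frame must be {FRAME_SIZE}x{FRAME_SIZE}")
            out[i] = self._embed_one(f)
        return out

    @staticmethod
    def _embed_one(f: np.ndarray) -> np.ndarray:
        mean = float(f.mean())
        sd = float(f.std())
        half = FRAME_SIZE // 4
        center = f[half:-half, half:-half]
        outer_mass = f.sum() - center.sum()
        q = np.quantile(f, [0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99])
        center_mean = float(center.mean())
        outer_mean = float(outer_mass / (f.size - center.size))
        # all summaries stay on the intensity scale of the frame itself, so no
        # single coordinate dominates the Euclidean distance downstream
        summary = np.array(
            [
                mean,
                sd,
                float(f.min()),
                float(f.max()),
                *q,
                center_mean,
                outer_mean,
                center_mean - outer_mean,
                float(np.median(np.abs(f - np.median(f)))),
            ]
        )
        centered = f - mean
        radial = (
            np.bincount(_RADIAL_IDX.ravel(), weights=centered.ravel(), minlength=_N_RADIAL)
            / _RADIAL_COUNTS
        )
        scaled = centered / (sd + 1e-9)
        hist, _ = np.histogram(scaled, bins=_N_HIST, range=(-4.0, 4.0))
        hist = hist / f.size
        return np.concatenate([summary, radial, hist])


# ---------------------------------------------------------------------------
# trainable classifier backend
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbedTrainingConfig:
    """Desk-scale settings for the classifier backend."""

    epochs: int = 60
    batch_size: int = 128
    hidden: tuple[int, int] = (256, EMBED_DIM)
    downsample: int = 2  # 2x2 average pooling of the 64x64 frame before the MLP
    learning_rate: float = 1e-3
    validation_field: int = 4  # frames from this field are held out


class ClassifierEmbedder:
    """Protein-classification MLP; the embedding is the activation of the
    128-unit penultimate hidden layer."""

    dim = EMBED_DIM

    def __init__(self, config: EmbedTrainingConfig | None = None, seed: int = 0):
        self.config = config or EmbedTrainingConfig()
        if self.config.hidden[-1] != EMBED_DIM:
            raise ValueError(f"penultimate layer must have width {EMBED_DIM}")
        self.seed = seed
        self._mlp = None

    def _pool(self, frames: np.ndarray) -> np.ndarray:
        d = self.config.downsample
        n = frames.shape[0]
        if d > 1:
            k = FRAME_SIZE // d
            frames = frames.reshape(n, k, d, k, d).mean(axis=(2, 4))
        return frames.reshape(n, -1)

    def fit(self, frames: list[np.ndarray], labels: list[str]) -> "ClassifierEmbedder":
        from sklearn.neural_network import MLPClassifier

        frames = np.asarray([np.asarray(f, dtype=float) for f in frames])
        labels = np.asarray(labels)
        if len(frames) != len(labels):
            raise ValueError("frames and labels must be paired")
        if len(np.unique(labels)) < 2:
            raise ValueError("training requires at least two protein classes")
        X = self._pool(frames)
        self._mlp = MLPClassifier(
            hidden_layer_sizes=self.config.hidden,
            max_iter=self.config.epochs,
            batch_size=min(self.config.batch_size, len(X)),
            learning_rate_init=self.config.learning_rate,
            random_state=self.seed,
        )
        self._mlp.fit(X, labels)
        return self

    def predict_label(self, frames: list[np.ndarray]) -> np.ndarray:
        if self._mlp is None:
            raise RuntimeError("embedder is not fitted")
        return self._mlp.predict(self._pool(np.asarray(frames, dtype=float)))

    def embed(self, frames: list[np.ndarray] | np.ndarray) -> np.ndarray:
        if self._mlp is None:
            raise RuntimeError("embedder is not fitted")
        frames = np.asarray([np.asarray(f, dtype=float) for f in frames])
        if len(frames) == 0:
            return np.empty((0, EMBED_DIM))
        if frames.shape[1:] != (FRAME_SIZE, FRAME_SIZE):
            raise ValueError(f"frames must be {FRAME_SIZE}x{FRAME_SIZE}")
        act = self._pool(frames)
        # forward pass up to (and including) the penultimate hidden layer
        for i in range(len(self._mlp.coefs_) - 1):
            act = act @ self._mlp.coefs_[i] + self._mlp.intercepts_[i]
            act = np.maximum(act, 0.0)  # relu, sklearn's default
        return act


def train_embedder(
    frames: list[np.ndarray],
    labels: list[str],
    config: EmbedTrainingConfig | None = None,
    backgrounds: list[str] | None = None,
    seed: int = 0,
) -> ClassifierEmbedder:
    """Train the classifier backend on wild-type-background frames.

    If ``backgrounds`` is given, any non-WT entry is rejected: the screen's
    embedding space is defined on unperturbed cells only, so deletion
    backgrounds never leak into training.
    """
    if backgrounds is not None:
        bad = {b for b in backgrounds if b != "WT"}
        if bad:
            raise ValueError(f"training frames must come from the WT background, got {sorted(bad)}")
    return ClassifierEmbedder(config, seed=seed).fit(frames, labels)


def embed(embedder, frames) -> np.ndarray:
    """128-d embedding per frame, via whichever backend is supplied."""
    frames = list(frames)
    if len(frames) == 0:
        return np.empty((0, EMBED_DIM))
    return embedder.embed(frames)
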