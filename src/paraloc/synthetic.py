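"""Synthetic fluorescence screens with planted ground truth.

The generator emulates a reciprocal paralog screen: for every paralog pair
(A, B), GFP-tagged A is imaged in a wild-type and in a B-deletion background
(and vice versa), with several fields per condition and several replicates.
Cells are non-overlapping ellipses carrying a parametric compartment pattern
(cytoplasmic fill, nuclear disk, ER ring, offset vacuole blob, punctae);
paralog-deletion effects are planted as a multiplicative abundance factor
and/or a mixing fraction of signal moved to a target compartment.  Instance
masks and all planted parameters are returned alongside the images, so every
downstream stage of the pipeline can be validated against ground truth.

Intensity statistics follow a Poisson-plus-Gaussian model on top of a
constant background offset, which is the standard simple description of
photon shot noise plus camera read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("cytoplasm", "nucleus", "ER", "vacuole", "punctae")

WT = "WT"
DELETION = "DELETION"
BACKGROUNDS = (WT, DELETION)


class ConfigurationError(ValueError):
    """Raised for inconsistent screen designs or truth tables."""


# ---------------------------------------------------------------------------
# design / truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a reciprocal paralog screen.

    Parameters
    ----------
    pairs
        True paralog pairs ``(protein_a, protein_b)``.
    controls
        Randomly paired proteins used as negative controls; disjoint from
        the true pairs.
    n_replicates, n_fields
        Replicates per condition and imaged fields per replicate.
    cells_per_field
        Inclusive ``(low, high)`` range of cells placed per field.
    image_size
        ``(rows, cols)`` of each field in pixels.
    """

    pairs: tuple[tuple[str, str], ...]
    controls: tuple[tuple[str, str], ...] = ()
    n_replicates: int = 3
    n_fields: int = 4
    cells_per_field: tuple[int, int] = (50, 100)
    image_size: tuple[int, int] = (512, 512)
    clump_fraction: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        object.__setattr__(self, "controls", tuple(tuple(p) for p in self.controls))
        seen: set[str] = set()
        for a, b in self.pairs + self.controls:
            for protein in (a, b):
                if protein in seen:
                    raise ConfigurationError(f"protein {protein!r} appears in more than one pair")
                seen.add(protein)
        lo, hi = self.cells_per_field
        if not (0 < lo <= hi):
            raise ConfigurationError("cells_per_field range must satisfy 0 < low <= high")
        if not (0.0 <= self.clump_fraction < 1.0):
            raise ConfigurationError("clump_fraction must be in [0, 1)")

    @property
    def all_pairs(self) -> tuple[tuple[str, str], ...]:
        return self.pairs + self.controls

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(p for pair in self.all_pairs for p in pair)

    def pair_of(self, protein: str) -> tuple[str, str]:
        for pair in self.all_pairs:
            if protein in pair:
                return pair
        raise KeyError(protein)

    def partner(self, protein: str) -> str:
        a, b = self.pair_of(protein)
        return b if protein == a else a


@dataclass(frozen=True)
class ProteinTruth:
    """Planted parameters for one GFP-tagged protein."""

    wt_compartment: str
    abundance_wt: float = 2000.0
    effect_abundance: float = 1.0
    effect_relocalization: float = 0.0
    target_compartment: str | None = None

    def __post_init__(self) -> None:
        if self.wt_compartment not in COMPARTMENTS:
            raise ConfigurationError(f"unknown compartment {self.wt_compartment!r}")
        if self.abundance_wt <= 0 or self.effect_abundance <= 0:
            raise ConfigurationError("abundance parameters must be strictly positive")
        if not (0.0 <= self.effect_relocalization <= 1.0):
            raise ConfigurationError("effect_relocalization must lie in [0, 1]")
        if self.effect_relocalization > 0:
            if self.target_compartment is None:
                raise ConfigurationError("relocalization requires a target compartment")
            if self.target_compartment not in COMPARTMENTS:
                raise ConfigurationError(f"unknown compartment {self.target_compartment!r}")

    @property
    def label_redistributed(self) -> bool:
        return self.effect_abundance != 1.0 or self.effect_relocalization > 0.0


class SimTruth:
    """Mapping protein -> :class:`ProteinTruth` with a tabular view."""

    def __init__(self, proteins: dict[str, ProteinTruth]):
        self.proteins = dict(proteins)

    def __getitem__(self, protein: str) -> ProteinTruth:
        return self.proteins[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self.proteins

    def __len__(self) -> int:
        return len(self.proteins)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.proteins.items():
            rows.append(
                {
                    "protein": name,
                    "wt_compartment": t.wt_compartment,
                    "abundance_wt": t.abundance_wt,
                    "effect_abundance": t.effect_abundance,
                    "effect_relocalization": t.effect_relocalization,
                    "target_compartment": t.target_compartment or "",
                    "label_redistributed": t.label_redistributed,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NoiseParams:
    """Poisson-plus-Gaussian noise on top of a constant background offset."""

    background_offset: float = 100.0
    read_noise_sd: float = 5.0
    poisson: bool = True

    @classmethod
    def noiseless(cls) -> "NoiseParams":
        return cls(background_offset=0.0, read_noise_sd=0.0, poisson=False)


@dataclass(frozen=True)
class CellGeometry:
    """An elliptical cell stencil in local coordinates."""

    semi_major: float
    semi_minor: float
    orientation: float = 0.0  # radians, CCW from the row axis


@dataclass
class SyntheticImage:
    pixels: np.ndarray  # uint16 intensity grid
    mask: np.ndarray  # uint16 instance labels, 0 = background
    protein: str
    background: str
    replicate: int
    field: int

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ConfigurationError("pixel grid and mask must share a shape")


# ---------------------------------------------------------------------------
# compartment templates
# ---------------------------------------------------------------------------

_BASELINE = {"cytoplasm": 1.0, "nucleus": 0.08, "ER": 0.15, "vacuole": 0.25, "punctae": 0.2}

# thin low-intensity rim at the very cell edge (cell-wall dip); it creates an
# intensity valley between touching cells that the watershed can exploit
_RIM_START = 0.92
_RIM_FACTOR = 0.05


def _local_grid(geometry: CellGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    half = int(math.ceil(max(geometry.semi_major, geometry.semi_minor))) + 2
    size = 2 * half + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    c, s = math.cos(geometry.orientation), math.sin(geometry.orientation)
    u = (rr * c + cc * s) / geometry.semi_major
    v = (-rr * s + cc * c) / geometry.semi_minor
    r = np.hypot(u, v)  # normalized elliptical radius, 1.0 at the boundary
    return r, u, v, size


def compartment_template(
    compartment: str, geometry: CellGeometry, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude intensity template and boolean stencil for one cell.

    Templates are parametric geometry: cytoplasmic fill, a bright nuclear
    disk, a peripheral ER ring, an off-center vacuolar blob, or scattered
    punctae.  Intensities are relative (peak structure = 1).
    """
    if compartment not in COMPARTMENTS:
        raise ConfigurationError(f"unknown compartment {compartment!r}")
    r, u, v, size = _local_grid(geometry)
    stencil = r <= 1.0
    base = _BASELINE[compartment]
    tmpl = np.where(stencil, base, 0.0)

    if compartment == "cytoplasm":
        pass
    elif compartment == "nucleus":
        tmpl[(r <= 0.45)] = 1.0
    elif compartment == "ER":
        tmpl[(r >= 0.68) & (r <= 0.90)] = 1.0
    elif compartment == "vacuole":
        blob = np.hypot(u - 0.30, v) <= 0.45
        tmpl[blob & stencil] = 1.0
    elif compartment == "punctae":
        if rng is None:
            rng = np.random.default_rng(0)
        n_dots = int(rng.integers(4, 8))
        half = size // 2
        rr, cc = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        for _ in range(n_dots):
            while True:
                du, dv = rng.uniform(-0.75, 0.75, size=2)
                if du * du + dv * dv <= 0.75**2:
                    break
            c0, s0 = math.cos(geometry.orientation), math.sin(geometry.orientation)
            dr = du * geometry.semi_major * c0 - dv * geometry.semi_minor * s0
            dc = du * geometry.semi_major * s0 + dv * geometry.semi_minor * c0
            dot = np.hypot(rr - dr, cc - dc) <= 2.0
            tmpl[dot & stencil] = 1.0

    rim = stencil & (r >= _RIM_START)
    tmpl[rim] *= _RIM_FACTOR
    # normalize to unit mean over the stencil: relocalization (template mixing)
    # then conserves total fluorescence, decoupling localization from abundance
    tmpl[stencil] /= tmpl[stencil].mean()
    return tmpl, stencil


def render_cell(
    compartment: str,
    abundance: float,
    cell_geometry: CellGeometry,
    noise_params: NoiseParams = NoiseParams.noiseless(),
    rng: np.random.Generator | None = None,
    mix: tuple[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell patch and its stencil.

    ``mix=(target, f)`` moves fraction ``f`` of the expected signal to the
    target compartment's template, as used for planted relocalization.
    Returns ``(pixels, stencil)`` where pixels are expected photon counts
    (noiseless) or a Poisson/Gaussian sample around them.
    """
    if abundance <= 0:
        raise ValueError("abundance must be strictly positive")
    if rng is None:
        rng = np.random.default_rng(0)
    tmpl, stencil = compartment_template(compartment, cell_geometry, rng)
    if mix is not None:
        target, f = mix
        if not (0.0 <= f <= 1.0):
            raise ValueError("mixing fraction must lie in [0, 1]")
        if f > 0:
            tmpl2, _ = compartment_template(target, cell_geometry, rng)
            tmpl = (1.0 - f) * tmpl + f * tmpl2
    expected = abundance * tmpl + noise_params.background_offset * stencil
    if noise_params.poisson:
        pixels = rng.poisson(expected).astype(float)
    else:
        pixels = expected.copy()
    if noise_params.read_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_params.read_noise_sd, size=pixels.shape)
    return np.clip(pixels, 0.0, None), stencil


# ---------------------------------------------------------------------------
# field / screen generation
# ---------------------------------------------------------------------------


def _place_cells(
    n_cells: int,
    image_size: tuple[int, int],
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (12.0, 16.0),
    clump_fraction: float = 0.1,
) -> list[tuple[float, float, CellGeometry]]:
    """Sample non-overlapping ellipse placements, with a controlled fraction
    of deliberately touching pairs to exercise watershed splitting."""
    rows, cols = image_size
    placements: list[tuple[float, float, CellGeometry]] = []
    max_tries = 300
    for i in range(n_cells):
        a = rng.uniform(*radius_range)
        b = a * rng.uniform(0.75, 1.0)
        geom = CellGeometry(semi_major=a, semi_minor=b, orientation=rng.uniform(0, math.pi))
        touch = placements and rng.uniform() < clump_fraction
        placed = False
        for _ in range(max_tries):
            if touch:
                pr, pc, pgeom = placements[int(rng.integers(len(placements)))]
                ang = rng.uniform(0, 2 * math.pi)
                d = (pgeom.semi_major + a) * 0.95
                r0, c0 = pr + d * math.cos(ang), pc + d * math.sin(ang)
            else:
                margin = a + 2
                r0 = rng.uniform(margin, rows - margin)
                c0 = rng.uniform(margin, cols - margin)
            if not (a + 1 <= r0 <= rows - a - 1 and a + 1 <= c0 <= cols - a - 1):
                continue
            ok = True
            for qr, qc, qgeom in placements:
                d = math.hypot(r0 - qr, c0 - qc)
                limit = (a + qgeom.semi_major) * (0.92 if touch else 1.05)
                if d < limit:
                    if touch and d > (a + qgeom.semi_major) * 0.80:
                        continue  # touching is allowed for clumped placement
                    ok = False
                    break
            if ok:
                placements.append((r0, c0, geom))
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"could not place cell {i + 1}/{n_cells} in a {rows}x{cols} image"
            )
    return placements


def render_field(
    protein: str,
    background: str,
    truth: ProteinTruth,
    design: ScreenDesign,
    rng: np.random.Generator,
    noise: NoiseParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one field for a (protein, background) condition."""
    rows, cols = design.image_size
    lo, hi = design.cells_per_field
    n_cells = int(rng.integers(lo, hi + 1))
    placements = _place_cells(n_cells, design.image_size, rng, clump_fraction=design.clump_fraction)

    abundance = truth.abundance_wt
    mix = None
    if background == DELETION:
        abundance *= truth.effect_abundance
        if truth.effect_relocalization > 0:
            mix = (truth.target_compartment, truth.effect_relocalization)

    expected = np.full((rows, cols), noise.background_offset, dtype=float)
    mask = np.zeros((rows, cols), dtype=np.uint16)
    best_r = np.full((rows, cols), np.inf)

    for label, (r0, c0, geom) in enumerate(placements, start=1):
        cell_noise = NoiseParams(background_offset=0.0, read_noise_sd=0.0, poisson=False)
        patch, stencil = render_cell(
            truth.wt_compartment, abundance, geom, cell_noise, rng=rng, mix=mix
        )
        r_local, _, _, size = _local_grid(geom)
        half = size // 2
        ri, ci = int(round(r0)), int(round(c0))
        rs, re = ri - half, ri + half + 1
        cs, ce = ci - half, ci + half + 1
        pr0, pr1 = max(0, -rs), size - max(0, re - rows)
        pc0, pc1 = max(0, -cs), size - max(0, ce - cols)
        rs, re, cs, ce = max(rs, 0), min(re, rows), max(cs, 0), min(ce, cols)
        sub = (slice(rs, re), slice(cs, ce))
        psub = (slice(pr0, pr1), slice(pc0, pc1))
        sten = stencil[psub]
        rloc = r_local[psub]
        # overlapping pixels of touching cells go to the nearer center
        claim = sten & (rloc < best_r[sub])
        expected[sub][claim] = noise.background_offset + patch[psub][claim]
        mask[sub][claim] = label
        best_r[sub][claim] = rloc[claim]

    # touching cells keep a dark wall: pixels on the contact line between two
    # labels drop to rim intensity (the per-cell rim is erased there by the
    # nearer-center claim, but real adjoining cells remain wall-separated)
    wall = np.zeros(mask.shape, dtype=bool)
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        sh = np.roll(mask, shift, axis=(0, 1))
        wall |= (mask > 0) & (sh > 0) & (sh != mask)
    expected[wall] = noise.background_offset + _RIM_FACTOR * (
        expected[wall] - noise.background_offset
    )

    if noise.poisson:
        pixels = rng.poisson(expected).astype(float)
    else:
        pixels = expected
    if noise.read_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise.read_noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0, 65535)
    # relabel consecutively in case a touching cell was fully claimed away
    mask = _relabel_consecutive(mask)
    return pixels.astype(np.uint16), mask


def _relabel_consecutive(mask: np.ndarray) -> np.ndarray:
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros_like(mask)
    for new, old in enumerate(labels, start=1):
        out[mask == old] = new
    return out


def generate_screen(
    design: ScreenDesign,
    truth: SimTruth,
    seed: int,
    noise: NoiseParams = NoiseParams(),
) -> tuple[list[SyntheticImage], pd.DataFrame]:
    """Generate every field of the screen, deterministically for a seed.

    Returns the list of :class:`SyntheticImage` (ordered by protein,
    background, replicate, field) and the planted-truth table.
    """
    for protein in design.proteins:
        if protein not in truth:
            raise ConfigurationError(f"no truth entry for protein {protein!r}")
    images: list[SyntheticImage] = []
    conditions = [
        (protein, background, rep, fld)
        for protein in design.proteins
        for background in BACKGROUNDS
        for rep in range(1, design.n_replicates + 1)
        for fld in range(1, design.n_fields + 1)
    ]
    seeds = np.random.SeedSequence(seed).spawn(len(conditions))
    for (protein, background, rep, fld), ss in zip(conditions, seeds):
        rng = np.random.default_rng(ss)
        pixels, mask = render_field(protein, background, truth[protein], design, rng, noise)
        images.append(SyntheticImage(pixels, mask, protein, background, rep, fld))
    return images, truth.to_frame()


# ---------------------------------------------------------------------------
# synthetic network tables
# ---------------------------------------------------------------------------


def generate_networks(
    design: ScreenDesign,
    truth: SimTruth,
    seed: int,
    planted_association: bool = True,
    n_background_genes: int = 300,
    shared_rate_redistributed: float = 8.0,
    shared_rate_null: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic PPI edges, genetic-interaction edges and localizations.

    When ``planted_association`` is on, pairs containing a redistributed
    protein receive a higher expected number of shared physical interactors
    and a strong negative within-pair genetic interaction (ε < 0, small p),
    so downstream network-feature comparisons have a detectable signal; when
    off, all pairs are exchangeable.
    """
    rng = np.random.default_rng(seed)
    universe = [f"g{i:04d}" for i in range(n_background_genes)]
    ppi_rows: list[dict] = []
    gi_rows: list[dict] = []
    loc_rows: list[dict] = []

    def add_ppi(a: str, b: str) -> None:
        ppi_rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "system_type": "physical",
                "throughput": "high",
                "study_id": f"S{int(rng.integers(1, 20)):03d}",
            }
        )

    for pair in design.all_pairs:
        a, b = pair
        redis = truth[a].label_redistributed or truth[b].label_redistributed
        if planted_association:
            shared_rate = shared_rate_redistributed if redis else shared_rate_null
        else:
            shared_rate = (shared_rate_redistributed + shared_rate_null) / 2.0
        n_shared = int(rng.poisson(shared_rate))
        shared = list(rng.choice(n_background_genes, size=min(n_shared, 50), replace=False))
        for g in shared:
            add_ppi(a, universe[g])
            add_ppi(b, universe[g])
        for protein in (a, b):
            n_private = int(rng.poisson(4.0)) + 1
            private = rng.choice(n_background_genes, size=n_private, replace=False)
            for g in private:
                if g not in shared:
                    add_ppi(protein, universe[g])
        # direct physical edge more likely for redistributed pairs when planted
        p_edge = 0.7 if (planted_association and redis) else 0.15
        if rng.uniform() < p_edge:
            add_ppi(a, b)
        # within-pair genetic interaction
        if planted_association and redis:
            eps = float(rng.normal(-0.45, 0.08))
            p = float(rng.uniform(0.0, 0.04))
        else:
            eps = float(rng.normal(0.0, 0.05))
            p = float(rng.uniform(0.0, 1.0))
        gi_rows.append({"gene_a": a, "gene_b": b, "epsilon": eps, "p": p})

        for protein in (a, b):
            t = truth[protein]
            comps = {t.wt_compartment}
            if t.target_compartment:
                comps.add(t.target_compartment)
            loc_rows.append({"protein": protein, "compartments": ";".join(sorted(comps))})

    # background gene-gene GI edges so the GI network is connected-ish
    n_bg_edges = n_background_genes
    for _ in range(n_bg_edges):
        i, j = rng.choice(n_background_genes, size=2, replace=False)
        gi_rows.append(
            {
                "gene_a": universe[i],
                "gene_b": universe[j],
                "epsilon": float(rng.normal(0.0, 0.12)),
                "p": float(rng.uniform(0.0, 1.0)),
            }
        )

    ppi = pd.DataFrame(ppi_rows).drop_duplicates(subset=["gene_a", "gene_b"], ignore_index=True)
    gi = pd.DataFrame(gi_rows)
    loc = pd.DataFrame(loc_rows)
    return ppi, gi, loc


# ---------------------------------------------------------------------------
# canned designs
# ---------------------------------------------------------------------------


def default_truth(
    design: ScreenDesign,
    rng_or_seed: int | np.random.Generator = 0,
    effect_pairs: Sequence[tuple[str, str]] | None = None,
    effect_abundance: float = 2.0,
    effect_relocalization: float = 0.6,
    secondary_relocalization: float = 0.35,
    abundance_wt: float = 2000.0,
) -> SimTruth:
    """Build a truth table planting effects on ``effect_pairs`` (default: all
    true pairs); controls and unlisted pairs stay null.

    Within each effect pair, one member receives the abundance effect plus a
    milder relocalization toward its partner's compartment, the other a pure
    relocalization — mirroring the common co-occurrence of abundance and
    localization changes on real screens, where purely brightness-driven
    redistribution is the hardest to detect.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    if effect_pairs is None:
        effect_pairs = design.pairs
    effect_set = {tuple(p) for p in effect_pairs}
    proteins: dict[str, ProteinTruth] = {}
    compartment_cycle = ["cytoplasm", "nucleus", "ER", "punctae", "vacuole"]
    for i, pair in enumerate(design.all_pairs):
        a, b = pair
        comp_a = compartment_cycle[(2 * i) % len(compartment_cycle)]
        comp_b = compartment_cycle[(2 * i + 1) % len(compartment_cycle)]
        abund_a = abundance_wt * rng.uniform(0.8, 1.25)
        abund_b = abundance_wt * rng.uniform(0.8, 1.25)
        if tuple(pair) in effect_set:
            proteins[a] = ProteinTruth(
                wt_compartment=comp_a,
                abundance_wt=abund_a,
                effect_abundance=effect_abundance,
                effect_relocalization=secondary_relocalization,
                target_compartment=comp_b,
            )
            proteins[b] = ProteinTruth(
                wt_compartment=comp_b,
                abundance_wt=abund_b,
                effect_relocalization=effect_relocalization,
                target_compartment=comp_a,
            )
        else:
            proteins[a] = ProteinTruth(wt_compartment=comp_a, abundance_wt=abund_a)
            proteins[b] = ProteinTruth(wt_compartment=comp_b, abundance_wt=abund_b)
    return SimTruth(proteins)


def demo_design(
    n_effect_pairs: int = 6,
    n_control_pairs: int = 2,
    n_replicates: int = 3,
    n_fields: int = 4,
    cells_per_field: tuple[int, int] = (60, 90),
    image_size: tuple[int, int] = (512, 512),
) -> ScreenDesign:
    """A desk-scale screen design: a handful of effect pairs plus
    random-pair negative controls."""
    pairs = tuple((f"P{i:02d}a", f"P{i:02d}b") for i in range(n_effect_pairs))
    controls = tuple(
        (f"C{i:02d}a", f"C{i:02d}b") for i in range(n_control_pairs)
    )
    return ScreenDesign(
        pairs=pairs,
        controls=controls,
        n_replicates=n_replicates,
        n_fields=n_fields,
        cells_per_field=cells_per_field,
        image_size=image_size,
    )


# ---------------------------------------------------------------------------
# two-channel validation fixtures (GFP + ER marker)
# ---------------------------------------------------------------------------


@dataclass
class TwoChannelImage:
    """One field of the two-channel validation experiment."""

    gfp: np.ndarray
    marker: np.ndarray
    mask: np.ndarray
    ring_mask: np.ndarray  # planted ER ring, ground truth for the marker
    strain: str
    replicate: int


def generate_two_channel_fields(
    n_cells_per_field: int = 30,
    n_fields_per_strain: int = 1,
    n_replicates: int = 3,
    strains: Sequence[str] = (WT, DELETION),
    gfp_effect: float = 2.0,
    image_size: tuple[int, int] = (896, 896),
    radius_range: tuple[float, float] = (36.0, 44.0),
    seed: int = 0,
    noise: NoiseParams = NoiseParams(background_offset=100.0, read_noise_sd=4.0),
) -> list[TwoChannelImage]:
    """Synthetic two-channel cells for the compartment quantification
    pipeline: a GFP channel (cytoplasmic fill, scaled by ``gfp_effect`` in
    the deletion strain) and an ER-marker channel whose ring comprises the
    brightest ~3% of each cell's pixels."""
    images: list[TwoChannelImage] = []
    seeds = np.random.SeedSequence(seed).spawn(len(strains) * n_replicates * n_fields_per_strain)
    k = 0
    for strain in strains:
        for rep in range(1, n_replicates + 1):
            for _ in range(n_fields_per_strain):
                rng = np.random.default_rng(seeds[k])
                k += 1
                rows, cols = image_size
                placements = _place_cells(
                    n_cells_per_field, image_size, rng, radius_range=radius_range,
                    clump_fraction=0.0,
                )
                gfp = np.full(image_size, noise.background_offset, dtype=float)
                marker = np.full(image_size, noise.background_offset, dtype=float)
                mask = np.zeros(image_size, dtype=np.uint16)
                ring = np.zeros(image_size, dtype=bool)
                amp = 1500.0 * (gfp_effect if strain == DELETION else 1.0)
                for label, (r0, c0, geom) in enumerate(placements, start=1):
                    r_local, _, _, size = _local_grid(geom)
                    sten = r_local <= 1.0
                    # thin ring: brightest ~3% of cell pixels by construction
                    ring_band = sten & (r_local >= 0.66) & (r_local <= 0.70)
                    marker_patch = np.where(ring_band, 3000.0, np.where(sten, 150.0, 0.0))
                    gfp_patch = np.where(sten, amp, 0.0)
                    half = size // 2
                    ri, ci = int(round(r0)), int(round(c0))
                    rs, re = ri - half, ri + half + 1
                    cs, ce = ci - half, ci + half + 1
                    if rs < 0 or cs < 0 or re > rows or ce > cols:
                        continue
                    sub = (slice(rs, re), slice(cs, ce))
                    gfp[sub][sten] += gfp_patch[sten]
                    marker[sub][sten] += marker_patch[sten]
                    mask[sub][sten] = label
                    ring[sub][ring_band] = True
                if noise.poisson:
                    gfp = rng.poisson(gfp).astype(float)
                    marker = rng.poisson(marker).astype(float)
                if noise.read_noise_sd > 0:
                    gfp += rng.normal(0, noise.read_noise_sd, gfp.shape)
                    marker += rng.normal(0, noise.read_noise_sd, marker.shape)
                images.append(
                    TwoChannelImage(
                        gfp=np.clip(gfp, 0, 65535).astype(np.uint16),
                        marker=np.clip(marker, 0, 65535).astype(np.uint16),
                        mask=mask,
                        ring_mask=ring,
                        strain=strain,
                        replicate=rep,
                    )
                )
    return images
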