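"""Seeded synthetic tissue and expression generators.

The generator emulates the statistical structure of cell-typed multiplexed
imaging of layered intestinal tissue: horizontal zones (mucosa, submucosa,
muscularis) with distinct cell-type compositions, crypt units carrying a
rare anchor type at their base, lymphoid follicles with inner/outer zones,
plasma-dense bands, and a two-group cohort (small bowel SB vs colon CL) with
planted composition shifts and group-restricted cell-cell attraction.  A
paired negative-binomial expression generator plants ligand/receptor
group-by-cell-type fold changes for the ligand-receptor pipeline.

Cell positions follow a homogeneous Poisson point process per zone so that
nearest-neighbour distance distributions have realistic variance.  All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .core import CellMap
from .exceptions import ConfigError

__all__ = [
    "ZoneSpec", "Band", "Crypt", "Follicle", "Attraction",
    "CohortConfig", "CovariateSpec", "Effect", "ExpressionConfig",
    "generate_tissue", "generate_cohort", "generate_expression",
    "default_zones", "default_structures", "default_cohort_config",
    "default_expression_config",
]

_TOL = 1e-9


def _validate_composition(comp: Mapping[str, float], what: str) -> dict:
    comp = {str(k): float(v) for k, v in comp.items()}
    if not comp:
        raise ConfigError(f"{what}: empty composition")
    if any(v < 0 for v in comp.values()):
        raise ConfigError(f"{what}: negative composition entry")
    s = sum(comp.values())
    if abs(s - 1.0) > 1e-6:
        raise ConfigError(f"{what}: composition sums to {s}, not 1")
    return comp


@dataclass(frozen=True)
class ZoneSpec:
    """A horizontal tissue band: [y0, y1) as fractions of tissue height,
    a Poisson intensity (cells per unit area) and a type composition."""

    name: str
    y_range: tuple[float, float]
    intensity: float
    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        y0, y1 = self.y_range
        if not (0.0 <= y0 < y1 <= 1.0):
            raise ConfigError(f"zone {self.name}: degenerate y_range {self.y_range}")
        if not self.intensity > 0:
            raise ConfigError(f"zone {self.name}: intensity must be > 0")
        object.__setattr__(self, "composition",
                           _validate_composition(self.composition, f"zone {self.name}"))


@dataclass(frozen=True)
class Band:
    """Full-width composition override inside a y-band (fractions of height)."""

    y_range: tuple[float, float]
    composition: Mapping[str, float]
    kind: str = field(default="band", init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "composition",
                           _validate_composition(self.composition, "band"))


@dataclass(frozen=True)
class Crypt:
    """Disk-shaped unit whose composition blends linearly from the override
    at the centre to the surrounding zone at the radius; ``anchor_count``
    cells of ``anchor_type`` are placed exactly at each centre."""

    centers: tuple[tuple[float, float], ...]
    radius: float
    composition: Mapping[str, float]
    anchor_type: str | None = None
    anchor_count: int = 0
    kind: str = field(default="crypt", init=False)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigError("crypt radius must be > 0")
        if self.anchor_count < 0:
            raise ConfigError("anchor_count must be >= 0")
        object.__setattr__(self, "composition",
                           _validate_composition(self.composition, "crypt"))


@dataclass(frozen=True)
class Follicle:
    """Concentric structure with distinct inner and outer compositions."""

    centers: tuple[tuple[float, float], ...]
    inner_radius: float
    outer_radius: float
    inner_composition: Mapping[str, float]
    outer_composition: Mapping[str, float]
    kind: str = field(default="follicle", init=False)

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ConfigError("follicle needs 0 < inner_radius < outer_radius")
        object.__setattr__(self, "inner_composition",
                           _validate_composition(self.inner_composition, "follicle inner"))
        object.__setattr__(self, "outer_composition",
                           _validate_composition(self.outer_composition, "follicle outer"))


@dataclass(frozen=True)
class Attraction:
    """Relocate a Bernoulli(strength) subset of source cells to a uniform
    point within ``radius`` of a random target cell — plants a controlled
    excess colocalization of source around target.  When ``group`` is set
    the structure applies only in cohort maps of that group."""

    source_type: str
    target_type: str
    strength: float
    radius: float
    group: str | None = None
    kind: str = field(default="attraction", init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ConfigError("attraction strength must lie in [0, 1]")
        if not self.radius > 0:
            raise ConfigError("attraction radius must be > 0")


Structure = Band | Crypt | Follicle | Attraction


def _check_zones(zones: Sequence[ZoneSpec]) -> None:
    if not zones:
        raise ConfigError("at least one zone required")
    spans = sorted((z.y_range for z in zones))
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1 - _TOL:
            raise ConfigError(f"zones overlap in y: {(a0, a1)} and {(b0, b1)}")


def _check_bounds(structures: Sequence[Structure], width: float, height: float) -> None:
    for s in structures:
        if isinstance(s, (Crypt, Follicle)):
            r = s.radius if isinstance(s, Crypt) else s.outer_radius
            for cx, cy in s.centers:
                if not (0 <= cx <= width and 0 <= cy <= height):
                    raise ConfigError(f"{s.kind} centre ({cx}, {cy}) outside tissue bounds")
                if r > max(width, height):
                    raise ConfigError(f"{s.kind} radius {r} exceeds tissue extent")
        elif isinstance(s, Band):
            y0, y1 = s.y_range
            if not (0.0 <= y0 < y1 <= 1.0):
                raise ConfigError(f"band y_range {s.y_range} outside [0, 1]")


def _draw_types(rng: np.random.Generator, probs: np.ndarray, types: list[str]) -> np.ndarray:
    """Per-row categorical draw: probs is (n, T), rows sum to 1."""
    u = rng.random(len(probs))
    cum = np.cumsum(probs, axis=1)
    cols = (cum > u[:, None]).argmax(axis=1)
    return np.asarray(types, dtype=object)[cols]


def generate_tissue(
    zones: Sequence[ZoneSpec],
    structures: Sequence[Structure] = (),
    *,
    width: float = 1000.0,
    height: float = 1000.0,
    noise: float = 0.0,
    seed: int = 0,
    sample_id: str = "S1",
    donor_id: str = "D1",
    region: str = "r1",
    group: str = "SB",
) -> CellMap:
    """Simulate one tissue section.

    Cells are a homogeneous Poisson process per zone; each cell's type is
    drawn from its zone's composition, overridden inside structures; anchor
    cells are placed exactly; finally a ``noise`` fraction of cells has its
    type resampled uniformly over the full type list (strictly degrading
    spatial signal).  Identical (config, seed) gives an identical CellMap.
    """
    if not (0.0 <= noise < 1.0):
        raise ConfigError(f"noise must lie in [0, 1), got {noise}")
    _check_zones(zones)
    _check_bounds(structures, width, height)
    rng = np.random.default_rng(seed)

    all_types: list[str] = sorted(
        set().union(*(z.composition for z in zones)),
    )
    for s in structures:
        if isinstance(s, Band):
            all_types = sorted(set(all_types) | set(s.composition))
        elif isinstance(s, Crypt):
            extra = set(s.composition) | ({s.anchor_type} if s.anchor_type else set())
            all_types = sorted(set(all_types) | extra)
        elif isinstance(s, Follicle):
            all_types = sorted(set(all_types) | set(s.inner_composition)
                               | set(s.outer_composition))

    def comp_vector(comp: Mapping[str, float]) -> np.ndarray:
        return np.array([comp.get(t, 0.0) for t in all_types], dtype=float)

    xs, ys, zone_of = [], [], []
    for zi, zone in enumerate(zones):
        y0, y1 = zone.y_range[0] * height, zone.y_range[1] * height
        n = rng.poisson(zone.intensity * width * (y1 - y0))
        xs.append(rng.uniform(0.0, width, n))
        ys.append(rng.uniform(y0, y1, n))
        zone_of.append(np.full(n, zi))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    zone_of = np.concatenate(zone_of)
    n = len(x)
    if n == 0:
        raise ConfigError("zone intensities produced an empty tissue")

    probs = np.vstack([comp_vector(zones[zi].composition) for zi in zone_of])

    # structure overrides (order: bands, then follicles, then crypts)
    for s in structures:
        if isinstance(s, Band):
            inside = (y >= s.y_range[0] * height) & (y < s.y_range[1] * height)
            probs[inside] = comp_vector(s.composition)
    for s in structures:
        if isinstance(s, Follicle):
            pin, pout = comp_vector(s.inner_composition), comp_vector(s.outer_composition)
            for cx, cy in s.centers:
                d = np.hypot(x - cx, y - cy)
                probs[d <= s.inner_radius] = pin
                probs[(d > s.inner_radius) & (d <= s.outer_radius)] = pout
    for s in structures:
        if isinstance(s, Crypt):
            pc = comp_vector(s.composition)
            for cx, cy in s.centers:
                d = np.hypot(x - cx, y - cy)
                w = np.clip(1.0 - d / s.radius, 0.0, 1.0)
                probs = probs * (1.0 - w[:, None]) + np.outer(w, pc)

    types = _draw_types(rng, probs, all_types)

    # exact anchors at crypt centres
    ax, ay, at = [], [], []
    for s in structures:
        if isinstance(s, Crypt) and s.anchor_type and s.anchor_count > 0:
            for cx, cy in s.centers:
                ax.extend([cx] * s.anchor_count)
                ay.extend([cy] * s.anchor_count)
                at.extend([s.anchor_type] * s.anchor_count)
    if ax:
        x = np.concatenate([x, np.array(ax)])
        y = np.concatenate([y, np.array(ay)])
        types = np.concatenate([types, np.array(at, dtype=object)])
        n = len(x)

    # attraction: relocate source cells near random targets
    for s in structures:
        if isinstance(s, Attraction) and s.strength > 0:
            src = np.flatnonzero(types == s.source_type)
            tgt = np.flatnonzero(types == s.target_type)
            if len(src) == 0 or len(tgt) == 0:
                continue
            move = src[rng.random(len(src)) < s.strength]
            anchors = tgt[rng.integers(0, len(tgt), len(move))]
            theta = rng.uniform(0, 2 * np.pi, len(move))
            rad = s.radius * np.sqrt(rng.random(len(move)))
            x[move] = np.clip(x[anchors] + rad * np.cos(theta), 0.0, width)
            y[move] = np.clip(y[anchors] + rad * np.sin(theta), 0.0, height)

    if noise > 0:
        flip = rng.random(n) < noise
        types[flip] = rng.choice(np.asarray(all_types, dtype=object), flip.sum())

    zone_names = [zones[zi].name for zi in zone_of] + ["anchor"] * len(ax)
    cells = pd.DataFrame({
        "cell_id": [f"{sample_id}-{i:06d}" for i in range(n)],
        "x": x,
        "y": y,
        "cell_type": types,
        "sample_id": sample_id,
        "donor_id": donor_id,
        "region": region,
        "group": group,
        "compartment": zone_names,
    })
    return CellMap(cells=cells, area=width * height)


def zone_assignment(cellmap: CellMap) -> np.ndarray:
    """The generating zone of each cell (stored in the compartment column)."""
    return cellmap.cells["compartment"].to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """Donor covariate linearly related to a cell-type fraction (BMI-like)."""

    cell_type: str
    slope: float = 0.0
    intercept: float = 25.0
    sd: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    """An n-donor, multi-region cohort with two anatomical groups."""

    zones: tuple[ZoneSpec, ...]
    structures: tuple[Structure, ...] = ()
    n_donors: int = 8
    regions: tuple[tuple[str, str], ...] = (("jejunum", "SB"), ("sigmoid", "CL"))
    group_deltas: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise: float = 0.05
    width: float = 1000.0
    height: float = 1000.0
    seed: int = 0
    covariate: CovariateSpec | None = None

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ConfigError("n_donors must be >= 1")
        if not (0.0 <= self.noise < 1.0):
            raise ConfigError("noise must lie in [0, 1)")
        groups = {g for _, g in self.regions}
        if not groups <= {"SB", "CL"}:
            raise ConfigError(f"region groups must be SB or CL, got {groups}")


def _shift_composition(comp: Mapping[str, float], delta: Mapping[str, float]) -> dict:
    shifted = {t: comp.get(t, 0.0) + delta.get(t, 0.0) for t in comp}
    shifted = {t: max(v, 0.0) for t, v in shifted.items()}
    s = sum(shifted.values())
    if s <= 0:
        raise ConfigError("composition shift drove all entries to zero")
    return {t: v / s for t, v in shifted.items()}


def generate_cohort(config: CohortConfig) -> tuple[list[CellMap], pd.DataFrame]:
    """Generate one CellMap per donor x region plus a donor metadata table.

    Group deltas are additive shifts applied to every zone composition of
    maps in that group (clipped at zero, renormalized).  Attraction
    structures carrying a ``group`` tag fire only in maps of that group.
    The donor covariate, when configured, is ``intercept + slope * f + eps``
    where ``f`` is the donor's pooled fraction of the chosen cell type.
    """
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.generate_state(config.n_donors * len(config.regions) + 1) % (2**31)
    maps: list[CellMap] = []
    k = 0
    for d in range(config.n_donors):
        donor = f"D{d + 1:02d}"
        for region, group in config.regions:
            delta = config.group_deltas.get(group, {})
            zones = tuple(
                dataclasses.replace(z, composition=_shift_composition(z.composition, delta))
                for z in config.zones
            )
            structures = tuple(
                s for s in config.structures
                if not (isinstance(s, Attraction) and s.group not in (None, group))
            )
            maps.append(generate_tissue(
                zones, structures,
                width=config.width, height=config.height,
                noise=config.noise, seed=int(child_seeds[k]),
                sample_id=f"{donor}-{region}", donor_id=donor,
                region=region, group=group,
            ))
            k += 1

    rng = np.random.default_rng(int(child_seeds[-1]))
    rows = []
    for d in range(config.n_donors):
        donor = f"D{d + 1:02d}"
        donor_maps = [m for m in maps if m.donor_id == donor]
        row: dict = {"donor_id": donor}
        if config.covariate is not None:
            cv = config.covariate
            total = sum(m.n for m in donor_maps)
            hits = sum((m.cell_types == cv.cell_type).sum() for m in donor_maps)
            frac = hits / total if total else np.nan
            row["covariate"] = cv.intercept + cv.slope * frac + rng.normal(0.0, cv.sd)
            row[f"fraction_{cv.cell_type}"] = frac
        rows.append(row)
    return maps, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Effect:
    """A planted log2 fold change for one gene in one cell type and group."""

    gene: str
    cell_type: str
    group: str
    log2fc: float


@dataclass(frozen=True)
class ExpressionConfig:
    genes: tuple[str, ...]
    cell_types: tuple[str, ...]
    groups: tuple[str, ...] = ("SB", "CL")
    baseline_mean: float = 5.0
    dispersion: float = 2.0
    effects: tuple[Effect, ...] = ()
    cells_per_type_per_group: int = 200

    def __post_init__(self) -> None:
        if not self.genes or not self.cell_types:
            raise ConfigError("need at least one gene and one cell type")
        if not self.baseline_mean > 0:
            raise ConfigError("baseline_mean must be > 0")
        if not self.dispersion > 0:
            raise ConfigError("dispersion must be > 0")
        if self.cells_per_type_per_group < 1:
            raise ConfigError("cells_per_type_per_group must be >= 1")
        for e in self.effects:
            if e.gene not in self.genes:
                raise ConfigError(f"effect gene {e.gene!r} not in gene list")
            if e.cell_type not in self.cell_types:
                raise ConfigError(f"effect cell type {e.cell_type!r} not in cell types")
            if e.group not in self.groups:
                raise ConfigError(f"effect group {e.group!r} not in groups")


def generate_expression(config: ExpressionConfig, seed: int = 0) -> ad.AnnData:
    """Negative-binomial cell x gene counts with planted group effects.

    Counts for gene g in (type t, group r) are NB with mean
    ``baseline_mean * 2 ** sum(log2fc of matching effects)`` and a fixed
    size/dispersion parameter, so variance/mean > 1 for every gene.
    """
    rng = np.random.default_rng(seed)
    genes = list(config.genes)
    blocks, obs_rows = [], []
    for t in config.cell_types:
        for r in config.groups:
            mu = np.full(len(genes), config.baseline_mean)
            for e in config.effects:
                if e.cell_type == t and e.group == r:
                    mu[genes.index(e.gene)] *= 2.0 ** e.log2fc
            size = config.dispersion
            p = size / (size + mu)
            nc = config.cells_per_type_per_group
            blocks.append(rng.negative_binomial(size, p, size=(nc, len(genes))))
            obs_rows.extend({"cell_type": t, "group": r, "sample_id": f"{t}-{r}"}
                            for _ in range(nc))
    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = genes
    return adata


# ---------------------------------------------------------------------------
# default study template (layered intestine)
# ---------------------------------------------------------------------------

MUCOSA = {
    "enterocyte": 0.34, "goblet": 0.10, "TA": 0.14, "stem": 0.06,
    "paneth": 0.01, "plasma": 0.16, "cd8_t": 0.09, "b_cell": 0.03,
    "macrophage": 0.04, "fibroblast": 0.02, "endothelial": 0.01,
}
SUBMUCOSA = {
    "fibroblast": 0.38, "endothelial": 0.20, "b_cell": 0.12, "plasma": 0.08,
    "cd8_t": 0.08, "macrophage": 0.08, "smooth_muscle": 0.05, "lymphatic": 0.01,
}
MUSCULARIS = {
    "smooth_muscle": 0.66, "fibroblast": 0.14, "endothelial": 0.08,
    "macrophage": 0.06, "cd8_t": 0.04, "icc": 0.02,
}


def default_zones(intensity: float = 0.01) -> tuple[ZoneSpec, ...]:
    """Mucosa / submucosa / muscularis bands; intensity in cells per unit^2
    (0.01 on a 1000x1000 tissue gives ~10,000 cells)."""
    return (
        ZoneSpec("mucosa", (0.0, 0.55), intensity, MUCOSA),
        ZoneSpec("submucosa", (0.55, 0.80), intensity, SUBMUCOSA),
        ZoneSpec("muscularis", (0.80, 1.0), intensity, MUSCULARIS),
    )


def default_structures(width: float = 1000.0, height: float = 1000.0) -> tuple[Structure, ...]:
    """Crypts with Paneth-like anchors along the mucosal base, one follicle
    with B-cell core, and a plasma-dense band under the crypts."""
    crypt_y = 0.50 * height
    crypt_centers = tuple((width * (i + 0.5) / 6.0, crypt_y) for i in range(6))
    crypt_comp = {"stem": 0.35, "TA": 0.45, "paneth": 0.08, "enterocyte": 0.12}
    follicle = Follicle(
        centers=((0.5 * width, 0.68 * height),),
        inner_radius=0.05 * width, outer_radius=0.10 * width,
        inner_composition={"b_cell": 0.75, "cd8_t": 0.15, "macrophage": 0.10},
        outer_composition={"cd8_t": 0.40, "b_cell": 0.25, "plasma": 0.25,
                           "macrophage": 0.10},
    )
    plasma_band = Band(y_range=(0.40, 0.48),
                      composition={"plasma": 0.55, "b_cell": 0.10, "cd8_t": 0.10,
                                   "enterocyte": 0.15, "TA": 0.10})
    return (
        plasma_band,
        follicle,
        Crypt(centers=crypt_centers, radius=0.04 * width,
              composition=crypt_comp, anchor_type="paneth", anchor_count=3),
    )


def default_cohort_config(
    *,
    n_donors: int = 8,
    intensity: float = 0.01,
    seed: int = 0,
    attraction_strength: float = 0.5,
) -> CohortConfig:
    """The default two-group cohort: SB and CL regions per donor, a colonic
    shift toward smooth muscle and away from endothelium, and a CL-only
    plasma-to-TA attraction (the planted colocalization signal)."""
    width = height = 1000.0
    structures = default_structures(width, height) + (
        Attraction(source_type="plasma", target_type="TA",
                   strength=attraction_strength, radius=20.0, group="CL"),
    )
    return CohortConfig(
        zones=default_zones(intensity),
        structures=structures,
        n_donors=n_donors,
        regions=(("jejunum", "SB"), ("ileum", "SB"),
                 ("ascending", "CL"), ("sigmoid", "CL")),
        group_deltas={"CL": {"smooth_muscle": 0.04, "endothelial": -0.02,
                             "plasma": 0.03}},
        noise=0.05,
        width=width, height=height,
        seed=seed,
        covariate=CovariateSpec(cell_type="macrophage", slope=200.0,
                                intercept=22.0, sd=1.0),
    )


def default_expression_config(
    *,
    n_genes: int = 100,
    n_planted: int = 10,
    log2fc: float = 1.5,
    cells_per_arm: int = 2000,
) -> ExpressionConfig:
    """Expression template with ligand/receptor gene pairs; the first
    ``n_planted`` pairs carry a +log2fc CL effect on both members (ligand in
    plasma, receptor in TA), emulating colon-upregulated signalling pairs."""
    n_pairs = n_genes // 2
    genes = tuple(f"L{i:03d}" for i in range(n_pairs)) + \
        tuple(f"R{i:03d}" for i in range(n_pairs))
    effects = []
    for i in range(n_planted):
        effects.append(Effect(f"L{i:03d}", "plasma", "CL", log2fc))
        effects.append(Effect(f"R{i:03d}", "TA", "CL", log2fc))
    return ExpressionConfig(
        genes=genes,
        cell_types=("plasma", "TA", "enterocyte", "fibroblast"),
        groups=("SB", "CL"),
        baseline_mean=5.0,
        dispersion=2.0,
        effects=tuple(effects),
        cells_per_type_per_group=cells_per_arm,
    )


def lr_pair_table(config: ExpressionConfig) -> pd.DataFrame:
    """The ligand-receptor pair table matching ``default_expression_config``
    (FANTOM5-style two-column frame: ligand, receptor)."""
    ligands = sorted(g for g in config.genes if g.startswith("L"))
    receptors = sorted(g for g in config.genes if g.startswith("R"))
    return pd.DataFrame({"ligand": ligands, "receptor": receptors,
                         "source": "synthetic"})
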