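"""Synthetic cohorts with the statistical structure the pipeline assumes.

Cell maps: TIL positions follow a Thomas (Poisson parent / Gaussian
offspring) cluster process, so the prognostic "TIL cluster" geometry is
under direct parametric control; non-TILs follow a homogeneous Poisson
process.  Four named archetypes — one per molecular subtype (CNH, CNL,
MSI, POLE) — rescale the TIL cluster parameters, coupling the spatial TIL
profile to the subtype label.  Patient-level risk is an explicit linear
predictor over realized (standardized) pipeline features; progression
times are exponential with hazard ``baseline_hazard * exp(risk)`` under
independent exponential censoring, and expression / mutation tables are
coupled to the same latent risk.

All randomness derives from one seed expanded into per-patient
substreams (``numpy.random.SeedSequence.spawn``), so any generated object
is a pure function of (config, seed) and patient order never changes
results.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import aggregate_patient, patient_feature_names
from .errors import InvalidConfigError, LayoutError
from .features import CellMap, extract_tile_features
from .masks import ProbMask
from .registry import default_registry

POPULATIONS = ("AA", "EA")
SUBTYPES = ("CNH", "CNL", "MSI", "POLE")


@dataclass
class ThomasParams:
    """Thomas cluster-process parameters for TILs.

    ``parent_intensity_mm2`` of None derives the parent rate from the
    configured TIL family intensity divided by ``mean_offspring``.
    """

    parent_intensity_mm2: float | None = None
    mean_offspring: float = 15.0
    sigma_um: float = 25.0


@dataclass
class Archetype:
    """Subtype-specific rescaling of the TIL cluster process."""

    til_intensity_scale: float = 1.0
    offspring_scale: float = 1.0
    sigma_scale: float = 1.0


def default_archetypes() -> dict[str, Archetype]:
    # immune infiltration increasing from CNH (cold) to POLE (hot),
    # mirroring the prognostic ordering of the molecular subtypes
    return {
        "CNH": Archetype(0.4, 1.0, 0.8),
        "CNL": Archetype(1.0, 1.0, 1.0),
        "MSI": Archetype(2.0, 1.3, 1.3),
        "POLE": Archetype(3.2, 1.6, 1.8),
    }


def separated_archetypes() -> dict[str, Archetype]:
    """Strongly separated TIL-profile archetypes for recovery studies.

    Each subtype occupies a distinct direction of the profile space:
    CNH cold with tight clusters, CNL moderate baseline, MSI diffuse
    large clusters, POLE hot with many small tight clusters.
    """
    return {
        "CNH": Archetype(0.5, 1.0, 0.6),
        "CNL": Archetype(1.0, 1.0, 1.0),
        "MSI": Archetype(3.0, 2.5, 2.8),
        "POLE": Archetype(6.0, 0.7, 0.7),
    }


def uniform_archetypes() -> dict[str, Archetype]:
    """Identical archetypes: subtype carries no TIL-profile information."""
    return {name: Archetype() for name in SUBTYPES}


@dataclass
class TileSpec:
    """Everything needed to simulate one tile's cell map."""

    compartment: str
    tile_size_um: float
    nontil_intensity_mm2: float
    til_parent_intensity_mm2: float
    til_mean_offspring: float
    til_sigma_um: float


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Intensities are cells per mm^2, rates are per month, lengths are
    microns.  Density defaults are order-of-magnitude choices (the kind of
    cellularity seen in H&E tiles) — no published distributional facts
    back them, and they are documented as such.
    """

    n_patients: int = 200
    population_mix: float = 0.3  # AA fraction
    tiles_per_patient: tuple[int, int] = (4, 8)
    tile_size_um: float = 500.0
    family_intensities_mm2: dict = field(default_factory=lambda: {
        ("epithelium", "TIL"): 300.0,
        ("epithelium", "nonTIL"): 800.0,
        ("stroma", "TIL"): 300.0,
        ("stroma", "nonTIL"): 500.0,
    })
    til_cluster_params: ThomasParams = field(default_factory=ThomasParams)
    jitter_sigma: float = 0.25  # lognormal sd of per-patient/compartment TIL jitter
    effect_vector: dict[str, float] = field(default_factory=dict)
    population_effect_vectors: dict[str, dict[str, float]] | None = None
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.015
    os_baseline_hazard: float = 0.012
    subtype_archetypes: dict[str, Archetype] = field(default_factory=default_archetypes)
    n_genes: int = 1000
    n_risk_genes: int = 30
    gene_effect: float = 0.6
    n_mutation_genes: int = 10
    mutation_base_rate: float = 0.3
    mutation_log_odds: float = -1.0  # negative: mutations enriched in low risk
    d_threshold_um: float = 50.0
    seed: int = 17

    def __post_init__(self):
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be positive")
        if not 0 <= self.population_mix <= 1:
            raise InvalidConfigError("population_mix must lie in [0, 1]")
        lo, hi = self.tiles_per_patient
        if lo < 1 or hi < lo:
            raise InvalidConfigError("tiles_per_patient range invalid")
        if not self.tile_size_um > 0:
            raise InvalidConfigError("tile_size_um must be positive")
        for key, val in self.family_intensities_mm2.items():
            if val < 0:
                raise InvalidConfigError(f"negative intensity for {key}")
        tp = self.til_cluster_params
        if tp.mean_offspring <= 0 or tp.sigma_um <= 0:
            raise InvalidConfigError("Thomas parameters must be positive")
        if tp.parent_intensity_mm2 is not None and tp.parent_intensity_mm2 < 0:
            raise InvalidConfigError("parent intensity must be nonnegative")
        if self.baseline_hazard <= 0 or self.os_baseline_hazard <= 0:
            raise InvalidConfigError("baseline hazards must be positive")
        if self.censoring_rate < 0:
            raise InvalidConfigError("censoring_rate must be nonnegative")
        if not 0 <= self.gene_effect <= 1:
            raise InvalidConfigError("gene_effect must lie in [0, 1]")
        if set(self.subtype_archetypes) != set(SUBTYPES):
            raise InvalidConfigError(f"archetypes must be named {SUBTYPES}")
        valid = set(patient_feature_names())
        for vec in self._effect_vectors().values():
            unknown = set(vec) - valid
            if unknown:
                raise InvalidConfigError(
                    f"effect_vector names unknown features: {sorted(unknown)[:5]}")

    def _effect_vectors(self) -> dict[str, dict[str, float]]:
        if self.population_effect_vectors:
            return {p: self.population_effect_vectors.get(p, self.effect_vector)
                    for p in POPULATIONS}
        return {p: self.effect_vector for p in POPULATIONS}

    def parent_intensity(self, compartment: str) -> float:
        tp = self.til_cluster_params
        if tp.parent_intensity_mm2 is not None:
            return tp.parent_intensity_mm2
        return self.family_intensities_mm2[(compartment, "TIL")] / tp.mean_offspring


@dataclass
class SyntheticPatient:
    patient_id: str
    population: str
    tiles: list[CellMap]
    true_risk: float
    pfs_time: float
    pfs_event: int
    os_time: float
    os_event: int
    subtype: str
    clinical: dict


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    features: pd.DataFrame  # patients x 4,200 realized pipeline features
    expression: pd.DataFrame  # genes x samples
    mutations: pd.DataFrame  # genes x samples, binary
    truth: dict

    def survival_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "time": p.pfs_time,
                   "event": p.pfs_event, "os_time": p.os_time,
                   "os_event": p.os_event, "population": p.population,
                   "subtype": p.subtype}
            row.update(p.clinical)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# point processes


def simulate_cell_map(spec: TileSpec, seed) -> CellMap:
    """Simulate one tile: Thomas-process TILs + Poisson non-TILs.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the same
    spec and seed always reproduce the identical centroid list.
    """
    if not spec.tile_size_um > 0:
        raise InvalidConfigError("tile size must be positive")
    if min(spec.nontil_intensity_mm2, spec.til_parent_intensity_mm2) < 0:
        raise InvalidConfigError("intensities must be nonnegative")
    rng = np.random.default_rng(seed)
    L = spec.tile_size_um
    area_mm2 = (L / 1000.0) ** 2

    # non-TILs: homogeneous Poisson
    n_non = rng.poisson(spec.nontil_intensity_mm2 * area_mm2)
    xy_non = rng.uniform(0, L, size=(n_non, 2))

    # TILs: Thomas process; parents live on a window padded by 4 sigma so
    # clusters seeded just outside the tile still contribute points
    pad = 4.0 * spec.til_sigma_um
    ext = L + 2 * pad
    ext_area_mm2 = (ext / 1000.0) ** 2
    n_parents = rng.poisson(spec.til_parent_intensity_mm2 * ext_area_mm2)
    pts = []
    for _ in range(n_parents):
        parent = rng.uniform(-pad, L + pad, size=2)
        n_off = rng.poisson(spec.til_mean_offspring)
        if n_off:
            off = parent + rng.normal(0.0, spec.til_sigma_um, size=(n_off, 2))
            keep = ((off >= 0) & (off < L)).all(axis=1)
            pts.append(off[keep])
    xy_til = np.vstack(pts) if pts else np.empty((0, 2))
    # guard the half-open interval against float round-up
    xy_til = np.clip(xy_til, 0.0, np.nextafter(L, 0.0))
    xy_non = np.clip(xy_non, 0.0, np.nextafter(L, 0.0))
    return CellMap.from_arrays("tile", spec.compartment, L, xy_til, xy_non)


def simulate_survival_times(risk: np.ndarray, baseline_hazard: float,
                            censoring_rate: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times at hazard h0*exp(risk), exponential censoring."""
    risk = np.asarray(risk, float)
    n = len(risk)
    u = rng.uniform(size=n)
    t_event = -np.log(u) / (baseline_hazard * np.exp(risk))
    if censoring_rate > 0:
        t_cens = rng.exponential(1.0 / censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # strictly positive times
    time = np.maximum(time, 1e-6)
    return time, event


# ---------------------------------------------------------------------------
# whole-cohort generation


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (tiles, features, survival, omics)."""
    registry = default_registry()
    root = np.random.SeedSequence(config.seed)
    patient_streams = root.spawn(config.n_patients)
    surv_stream, gene_stream, clin_stream = root.spawn(3)

    vecs = config._effect_vectors()
    patients_raw = []
    feature_rows = []
    for i, ss in enumerate(patient_streams):
        rng = np.random.default_rng(ss)
        pid = f"P{i:04d}"
        population = "AA" if rng.uniform() < config.population_mix else "EA"
        subtype = SUBTYPES[rng.integers(len(SUBTYPES))]
        arch = config.subtype_archetypes[subtype]
        n_tiles = int(rng.integers(config.tiles_per_patient[0],
                                   config.tiles_per_patient[1] + 1))
        # per-patient, per-compartment lognormal jitter of the TIL process
        jit = {comp: {
            "intensity": float(rng.lognormal(0.0, config.jitter_sigma)),
            "sigma": float(rng.lognormal(0.0, config.jitter_sigma)),
        } for comp in ("epithelium", "stroma")}
        tiles = []
        tile_vectors = []
        for t in range(n_tiles):
            comp = "epithelium" if t % 2 == 0 else "stroma"
            spec = TileSpec(
                compartment=comp,
                tile_size_um=config.tile_size_um,
                nontil_intensity_mm2=config.family_intensities_mm2[(comp, "nonTIL")],
                til_parent_intensity_mm2=(config.parent_intensity(comp)
                                          * arch.til_intensity_scale
                                          * jit[comp]["intensity"]),
                til_mean_offspring=(config.til_cluster_params.mean_offspring
                                    * arch.offspring_scale),
                til_sigma_um=(config.til_cluster_params.sigma_um
                              * arch.sigma_scale * jit[comp]["sigma"]),
            )
            cm = simulate_cell_map(spec, ss.spawn(1)[0])
            cm.tile_id = f"{pid}_t{t:02d}"
            tiles.append(cm)
            tile_vectors.append(extract_tile_features(
                cm, registry, config.d_threshold_um))
        feats = aggregate_patient(tile_vectors, pid, registry)
        feature_rows.append(feats)
        clin_rng = np.random.default_rng(ss.spawn(1)[0])
        clinical = {
            "age": float(np.round(clin_rng.normal(65.0, 8.0), 1)),
            "stage": str(clin_rng.choice(["I", "II", "III", "IV"],
                                         p=[0.55, 0.15, 0.2, 0.1])),
            "grade": int(clin_rng.choice([1, 2, 3], p=[0.3, 0.35, 0.35])),
        }
        patients_raw.append(dict(patient_id=pid, population=population,
                                 subtype=subtype, tiles=tiles,
                                 clinical=clinical, jitter=jit))

    features = pd.DataFrame(feature_rows)

    # cohort-standardized features define the latent linear predictor
    mat = features.to_numpy(float)
    with warnings.catch_warnings():
        # a compartment with no tiles anywhere yields all-NaN columns
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(mat, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    mat = np.where(np.isfinite(mat), mat, med)
    sd = mat.std(axis=0)
    z = np.where(sd > 0, (mat - mat.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=features.index, columns=features.columns)

    risks = np.zeros(config.n_patients)
    for i, praw in enumerate(patients_raw):
        vec = vecs[praw["population"]]
        risks[i] = sum(coef * zdf.iloc[i][name] for name, coef in vec.items())

    rng_surv = np.random.default_rng(surv_stream)
    pfs_time, pfs_event = simulate_survival_times(
        risks, config.baseline_hazard, config.censoring_rate, rng_surv)
    os_time, os_event = simulate_survival_times(
        risks, config.os_baseline_hazard, config.censoring_rate, rng_surv)

    patients = []
    for i, praw in enumerate(patients_raw):
        patients.append(SyntheticPatient(
            patient_id=praw["patient_id"], population=praw["population"],
            tiles=praw["tiles"], true_risk=float(risks[i]),
            pfs_time=float(pfs_time[i]), pfs_event=int(pfs_event[i]),
            os_time=float(os_time[i]), os_event=int(os_event[i]),
            subtype=praw["subtype"], clinical=praw["clinical"]))

    expression, mutations, risk_genes = _simulate_omics(
        config, risks, [p.patient_id for p in patients], gene_stream)

    truth = {
        "config": _config_dict(config),
        "true_risk": {p.patient_id: p.true_risk for p in patients},
        "jitter": {praw["patient_id"]: praw["jitter"] for praw in patients_raw},
        "risk_genes": risk_genes,
        "archetype": {p.patient_id: p.subtype for p in patients},
    }
    return SyntheticCohort(patients=patients, features=features,
                           expression=expression, mutations=mutations,
                           truth=truth)


def _simulate_omics(config: SimConfig, risks: np.ndarray, ids: list[str],
                    stream) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    rng = np.random.default_rng(stream)
    n = len(ids)
    sd = risks.std()
    z = (risks - risks.mean()) / sd if sd > 0 else np.zeros(n)
    ge = config.gene_effect
    genes = [f"G{j:04d}" for j in range(config.n_genes)]
    expr = np.empty((config.n_genes, n))
    for j in range(config.n_genes):
        noise = rng.normal(size=n)
        if j < config.n_risk_genes:
            signal = ge * z + math.sqrt(max(0.0, 1 - ge ** 2)) * noise
        else:
            signal = noise
        expr[j] = np.clip(100.0 + 20.0 * signal, 0.0, None)
    expression = pd.DataFrame(expr, index=genes, columns=ids)

    mut_genes = [f"MUT{j:02d}" for j in range(config.n_mutation_genes)]
    logit0 = math.log(config.mutation_base_rate / (1 - config.mutation_base_rate))
    p = 1.0 / (1.0 + np.exp(-(logit0 + config.mutation_log_odds * z)))
    muts = (rng.uniform(size=(config.n_mutation_genes, n)) < p).astype(int)
    mutations = pd.DataFrame(muts, index=mut_genes, columns=ids)
    return expression, mutations, genes[: config.n_risk_genes]


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["family_intensities_mm2"] = {
        f"{comp}:{fam}": v
        for (comp, fam), v in config.family_intensities_mm2.items()}
    return d


# ---------------------------------------------------------------------------
# probability-mask fixtures


def simulate_probability_mask(component_areas_px: list[int],
                              image_shape: tuple[int, int],
                              seed: int = 0) -> tuple[ProbMask, list[dict]]:
    """Binary-valued probability mask with components of exact pixel areas.

    Components are raster-filled blobs (probability 1.0 inside) packed on
    shelves with a 2-pixel background margin so they never merge under
    8-connectivity.  Returns the mask and per-component bookkeeping
    (requested area, bounding box).  Raises :class:`LayoutError` when the
    components cannot be packed.
    """
    h, w = image_shape
    values = np.zeros((h, w), dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(component_areas_px))
    margin = 2
    x = y = margin
    shelf_h = 0
    components = []
    for k in order:
        area = int(component_areas_px[k])
        if area <= 0:
            raise LayoutError("component areas must be positive")
        bw = max(1, math.ceil(math.sqrt(area)))
        full_rows, rem = divmod(area, bw)
        bh = full_rows + (1 if rem else 0)
        if x + bw + margin > w:
            x = margin
            y += shelf_h + margin
            shelf_h = 0
        if x + bw > w - 0 or y + bh + 0 > h:
            raise LayoutError(
                f"cannot pack component of {area} px into {image_shape}")
        block = np.zeros((bh, bw), dtype=bool)
        flat = block.ravel()
        flat[:area] = True
        values[y:y + bh, x:x + bw] = flat.reshape(bh, bw)
        components.append({"area_px": area, "x0": x, "y0": y,
                           "width": bw, "height": bh})
        x += bw + margin
        shelf_h = max(shelf_h, bh)
    components.sort(key=lambda c: (c["y0"], c["x0"]))
    return ProbMask(values), components


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write cells.csv, survival.csv, expression.tsv, mutations.tsv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        for cm in p.tiles:
            for _, c in cm.cells.iterrows():
                rows.append({"patient_id": p.patient_id, "slide_id": "S0",
                             "tile_id": cm.tile_id,
                             "compartment": cm.compartment,
                             "x_um": c["x_um"], "y_um": c["y_um"],
                             "family": c["family"],
                             "tile_size_um": cm.tile_size_um})
    pd.DataFrame(rows).to_csv(out / "cells.csv", index=False)
    cohort.survival_frame().to_csv(out / "survival.csv", index=False)
    cohort.features.rename_axis("patient_id").to_csv(out / "patient_features.csv")
    cohort.expression.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
    cohort.mutations.rename_axis("gene").to_csv(out / "mutations.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, default=str)


def load_cells(path) -> list[CellMap]:
    """Read a cells.csv table back into per-tile CellMaps."""
    df = pd.read_csv(path)
    maps = []
    for (tile_id, comp, size), grp in df.groupby(
            ["tile_id", "compartment", "tile_size_um"], sort=True):
        maps.append(CellMap(str(tile_id), comp, float(size),
                            grp[["x_um", "y_um", "family"]].copy()))
    return maps
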