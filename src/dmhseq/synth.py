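"""Synthetic dorsomedial-hypothalamus (DMH) count-data generator.

Emulates a pooled two-genotype (wild-type vs RII-beta knockout) DMH
dissection: eight coarse cell classes with canonical markers, neurons split
into GABAergic and glutamatergic subtypes, negative-binomial UMI counts with
lognormal cell library sizes and class-specific mitochondrial read
fractions, and genotype effects on designated genes and gene sets (a fully
ablated PKA regulatory subunit, a ~1.5-fold compensatory up-shift of
another, coordinated shifts of a PKA-activity set and a GABA-transport set).
Every draw is tied to one seed; identical configs reproduce byte-identical
matrices, and the matching :class:`GroundTruth` carries the per-cell and
per-gene labels the recovery tests score against.

The negative binomial is parameterised by mean ``mu`` and dispersion ``phi``
with ``variance = mu + phi * mu**2``.
"""
from __future__ import annotations

import dataclasses
import math
import tomllib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

LOG2_FOLD_1_5 = math.log2(1.5)

#: canonical marker scheme: one hallmark gene per non-neuronal class
NON_NEURONAL_MARKERS: dict[str, tuple[str, ...]] = {
    "astrocytes": ("Agt",),
    "endothelial": ("Flt1",),
    "microglia": ("Cx3cr1",),
    "oligodendrocytes": ("Opalin",),
    "opc": ("Pdgfra",),
    "pericytes": ("Vtn",),
    "vsm": ("Acta2",),
}
NEURON_MARKERS = ("Snap25", "Syp", "Tubb3", "Elavl2")
GABA_MARKERS = ("Slc32a1", "Gad1", "Gad2")
GLUT_MARKERS = ("Slc17a6",)
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Nd4", "mt-Co1", "mt-Co2",
    "mt-Co3", "mt-Atp6", "mt-Cytb", "mt-Rnr1", "mt-Rnr2",
)
PKA_ACTIVITY_GENES = (
    "Prkar1a", "Prkar1b", "Prkar2a", "Prkar2b",
    "Prkaca", "Prkacb", "Prkx", "Pkia",
)
GABA_TRANSPORT_GENES = (
    "Slc6a1", "Slc6a11", "Abat", "Gabra1", "Gabra2",
    "Gabrb1", "Gabrb3", "Gabbr1", "Gabbr2", "Gphn",
)

CLASSES = (
    "astrocytes", "endothelial", "microglia", "neurons",
    "oligodendrocytes", "opc", "pericytes", "vsm",
)
#: finest generative labels: non-neuronal classes plus the two neuron subtypes
SUBCLASSES = (
    "astrocytes", "endothelial", "microglia",
    "neurons_gaba", "neurons_glut",
    "oligodendrocytes", "opc", "pericytes", "vsm",
)


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


def _default_proportions() -> dict[str, float]:
    return {
        "neurons": 0.60,
        "astrocytes": 0.12,
        "oligodendrocytes": 0.08,
        "opc": 0.05,
        "microglia": 0.05,
        "endothelial": 0.04,
        "pericytes": 0.03,
        "vsm": 0.03,
    }


def _default_condition_effects() -> dict[str, float]:
    # full ablation of the knocked-out regulatory subunit and the observed
    # ~50% compensatory increase of Prkar1a
    return {"Prkar2b": float("-inf"), "Prkar1a": LOG2_FOLD_1_5}


def _default_effect_sets() -> dict[str, tuple[tuple[str, ...], float]]:
    return {
        "PKA_activity": (PKA_ACTIVITY_GENES, -LOG2_FOLD_1_5),
        "GABA_transport": (GABA_TRANSPORT_GENES, LOG2_FOLD_1_5),
    }


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic DMH experiment.

    ``condition_labels[0]`` is the reference genotype (WT); all condition
    effects apply to ``condition_labels[1]``.  Per-gene ``condition_effects``
    override set-level ``effect_gene_sets`` entries for the same gene.
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 1500
    cell_class_proportions: Mapping[str, float] = dataclasses.field(
        default_factory=_default_proportions
    )
    gaba_fraction: float = 0.55  # of neurons
    marker_fold: float = 20.0
    n_extra_markers: int = 15  # additional program genes per subclass
    base_mean_lognormal: tuple[float, float] = (0.0, 1.3)
    marker_base_mean_floor: float = 2.0
    nb_dispersion: float = 0.15
    nb_dispersion_bulk: float = 0.05
    libsize_lognormal: tuple[float, float] = (0.0, 0.35)
    mito_fraction: Mapping[str, float] | float = 0.05
    bulk_depth: float = 50.0
    condition_effects: Mapping[str, float] = dataclasses.field(
        default_factory=_default_condition_effects
    )
    effect_gene_sets: Mapping[str, tuple[Sequence[str], float]] = dataclasses.field(
        default_factory=_default_effect_sets
    )
    #: per-class lognormal activity factor shared by these sets (couples them)
    coupled_activity_sets: tuple[str, ...] = ("PKA_activity", "GABA_transport")
    class_activity_sigma: float = 0.4
    condition_labels: tuple[str, str] = ("WT", "KO")
    n_samples_per_condition: int = 5
    seed: int = 0

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_cells_per_condition < 1:
            raise ConfigError("n_cells_per_condition must be positive")
        props = dict(self.cell_class_proportions)
        unknown = set(props) - set(CLASSES)
        if unknown:
            raise ConfigError(
                f"cell_class_proportions has unknown classes: {sorted(unknown)}"
            )
        if any(p < 0 for p in props.values()):
            raise ConfigError("cell_class_proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("cell_class_proportions must sum to 1 within 1e-9")
        if not 0.0 <= self.gaba_fraction <= 1.0:
            raise ConfigError("gaba_fraction must lie in [0, 1]")
        for field in ("marker_fold", "nb_dispersion", "nb_dispersion_bulk",
                      "marker_base_mean_floor", "bulk_depth"):
            if getattr(self, field) <= 0:
                raise ConfigError(f"{field} must be strictly positive")
        if self.base_mean_lognormal[1] < 0 or self.libsize_lognormal[1] < 0:
            raise ConfigError("lognormal sigma must be non-negative "
                              "(base_mean_lognormal / libsize_lognormal)")
        for cls, f in self._mito_by_class().items():
            if not 0.0 <= f < 1.0:
                raise ConfigError(f"mito_fraction for {cls} must lie in [0, 1)")
        if self.class_activity_sigma < 0:
            raise ConfigError("class_activity_sigma must be non-negative")
        if self.n_extra_markers < 0:
            raise ConfigError("n_extra_markers must be non-negative")
        named = len(self._named_genes()) + len(MITO_GENES)
        if self.n_genes < named:
            raise ConfigError(
                f"n_genes must be at least {named} to hold all named genes"
            )

    def _mito_by_class(self) -> dict[str, float]:
        if isinstance(self.mito_fraction, Mapping):
            out = {c: 0.05 for c in SUBCLASSES}
            out.update(self.mito_fraction)
            return out
        return {c: float(self.mito_fraction) for c in SUBCLASSES}

    def _named_genes(self) -> list[str]:
        """All non-mitochondrial genes with designated roles, in fixed order."""
        names: list[str] = []
        for markers in NON_NEURONAL_MARKERS.values():
            names.extend(markers)
        names.extend(NEURON_MARKERS)
        names.extend(GABA_MARKERS)
        names.extend(GLUT_MARKERS)
        for genes, _ in self.effect_gene_sets.values():
            names.extend(g for g in genes if g not in names)
        names.extend(g for g in self.condition_effects if g not in names)
        for sub in SUBCLASSES:
            names.extend(f"{sub}-mk{i + 1:02d}" for i in range(self.n_extra_markers))
        return names

    # -------------------------------------------------------------- config IO
    def to_toml(self, path: str | Path) -> None:
        """Write the config as a flat TOML file (the documented dialect)."""
        lines = ["[generator]"]

        def fmt(v):
            if isinstance(v, bool):
                return str(v).lower()
            if isinstance(v, float):
                if math.isinf(v):
                    return "-inf" if v < 0 else "inf"
                return repr(v)
            if isinstance(v, int):
                return str(v)
            if isinstance(v, str):
                return f'"{v}"'
            if isinstance(v, (list, tuple)):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            raise TypeError(type(v))

        for field in ("n_genes", "n_cells_per_condition", "gaba_fraction",
                      "marker_fold", "n_extra_markers", "base_mean_lognormal",
                      "marker_base_mean_floor", "nb_dispersion",
                      "nb_dispersion_bulk", "libsize_lognormal", "bulk_depth",
                      "coupled_activity_sets", "class_activity_sigma",
                      "condition_labels", "n_samples_per_condition", "seed"):
            lines.append(f"{field} = {fmt(getattr(self, field))}")
        lines.append("\n[generator.cell_class_proportions]")
        for k, v in self.cell_class_proportions.items():
            lines.append(f"{k} = {fmt(float(v))}")
        lines.append("\n[generator.mito_fraction]")
        for k, v in self._mito_by_class().items():
            lines.append(f"{k} = {fmt(float(v))}")
        lines.append("\n[generator.condition_effects]")
        for k, v in self.condition_effects.items():
            lines.append(f"{k} = {fmt(float(v))}")
        for name, (genes, lfc) in self.effect_gene_sets.items():
            lines.append(f"\n[generator.effect_gene_sets.{name}]")
            lines.append(f"genes = {fmt(list(genes))}")
            lines.append(f"log2fc = {fmt(float(lfc))}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)["generator"]
        raw["effect_gene_sets"] = {
            name: (tuple(entry["genes"]), float(entry["log2fc"]))
            for name, entry in raw.get("effect_gene_sets", {}).items()
        }
        for field in ("base_mean_lognormal", "libsize_lognormal",
                      "condition_labels", "coupled_activity_sets"):
            if field in raw:
                raw[field] = tuple(raw[field])
        return cls(**raw)


@dataclasses.dataclass
class GroundTruth:
    """Generator truth: per-cell/sample and per-gene labels plus the seed."""

    cells: pd.DataFrame  # cell_id, condition, sample, cell_class, nt_class,
    #                      subclass, lib_factor, mito_fraction
    genes: pd.DataFrame  # gene_id, base_mean, marker_of, true_log2fc,
    #                      gene_sets, is_mito
    seed: int
    condition_labels: tuple[str, str]

    def fine_classes(self) -> np.ndarray:
        """Finest cell partition: classes with neurons split by subtype."""
        return self.cells["subclass"].to_numpy()

    def neuron_mask(self) -> np.ndarray:
        return (self.cells["cell_class"] == "neurons").to_numpy()

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / "truth_cells.tsv", sep="\t", index=False)
        self.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
        meta = pd.DataFrame(
            {"seed": [self.seed],
             "condition_a": [self.condition_labels[0]],
             "condition_b": [self.condition_labels[1]]}
        )
        meta.to_csv(directory / "truth_meta.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "GroundTruth":
        directory = Path(directory)
        cells = pd.read_csv(directory / "truth_cells.tsv", sep="\t",
                            keep_default_na=False)
        genes = pd.read_csv(directory / "truth_genes.tsv", sep="\t",
                            keep_default_na=False)
        genes["base_mean"] = pd.to_numeric(genes["base_mean"], errors="coerce")
        meta = pd.read_csv(directory / "truth_meta.tsv", sep="\t").iloc[0]
        return cls(cells, genes, int(meta["seed"]),
                   (str(meta["condition_a"]), str(meta["condition_b"])))


# --------------------------------------------------------------------- build
def _gene_table(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the gene universe: ids, base means, marker roles, effects, sets."""
    named = config._named_genes()
    n_filler = config.n_genes - len(named) - len(MITO_GENES)
    taken = set(named) | set(MITO_GENES)
    filler: list[str] = []
    i = 0
    while len(filler) < n_filler:
        i += 1
        name = f"gene{i:05d}"
        if name not in taken:
            filler.append(name)
    gene_ids = named + filler + list(MITO_GENES)
    mu, sigma = config.base_mean_lognormal
    base = rng.lognormal(mu, sigma, size=config.n_genes)

    marker_of = {g: "" for g in gene_ids}
    for cls, markers in NON_NEURONAL_MARKERS.items():
        for g in markers:
            marker_of[g] = cls
    for g in NEURON_MARKERS:
        marker_of[g] = "neurons"
    for g in GABA_MARKERS:
        marker_of[g] = "neurons_gaba"
    for g in GLUT_MARKERS:
        marker_of[g] = "neurons_glut"
    for sub in SUBCLASSES:
        for i in range(config.n_extra_markers):
            marker_of[f"{sub}-mk{i + 1:02d}"] = sub

    sets_of: dict[str, list[str]] = {g: [] for g in gene_ids}
    log2fc = {g: 0.0 for g in gene_ids}
    for name, (genes, lfc) in config.effect_gene_sets.items():
        for g in genes:
            sets_of[g].append(name)
            log2fc[g] = float(lfc)
    for g, lfc in config.condition_effects.items():
        log2fc[g] = float(lfc)

    frame = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": base,
            "marker_of": [marker_of[g] for g in gene_ids],
            "true_log2fc": [log2fc[g] for g in gene_ids],
            "gene_sets": [",".join(sets_of[g]) for g in gene_ids],
            "is_mito": [g in MITO_GENES for g in gene_ids],
        }
    )
    # canonical markers and designated effect genes are well expressed
    floored = (frame["marker_of"] != "") | (frame["gene_sets"] != "") | (
        frame["gene_id"].isin(list(config.condition_effects))
    )
    frame.loc[floored & ~frame["is_mito"], "base_mean"] = np.maximum(
        frame.loc[floored & ~frame["is_mito"], "base_mean"],
        config.marker_base_mean_floor,
    )
    frame.loc[frame["is_mito"], ["marker_of", "gene_sets"]] = ""
    frame.loc[frame["is_mito"], "true_log2fc"] = 0.0
    return frame


def _class_mean_matrix(
    config: GeneratorConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Expected mean per (non-mito gene, subclass) before library scaling."""
    nonmito = genes.loc[~genes["is_mito"]].reset_index(drop=True)
    G = len(nonmito)
    fold = np.ones((G, len(SUBCLASSES)))
    sub_idx = {c: i for i, c in enumerate(SUBCLASSES)}
    for i, row in nonmito.iterrows():
        mk = row["marker_of"]
        if mk == "neurons":
            fold[i, sub_idx["neurons_gaba"]] = config.marker_fold
            fold[i, sub_idx["neurons_glut"]] = config.marker_fold
        elif mk:
            fold[i, sub_idx[mk]] = config.marker_fold
    # per-class activity factor shared across the coupled gene sets:
    # classes with high activity lift both sets together
    activity = rng.lognormal(0.0, config.class_activity_sigma, len(SUBCLASSES))
    coupled = nonmito["gene_sets"].str.split(",").apply(
        lambda names: any(n in config.coupled_activity_sets for n in names if n)
    ).to_numpy()
    act = np.ones((G, len(SUBCLASSES)))
    act[coupled] = activity[None, :]
    return nonmito["base_mean"].to_numpy()[:, None] * fold * act


def _condition_multiplier(genes: pd.DataFrame) -> np.ndarray:
    lfc = genes.loc[~genes["is_mito"], "true_log2fc"].to_numpy()
    mult = np.power(2.0, lfc)
    mult[np.isneginf(lfc)] = 0.0
    return mult


def _nb_sample(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """NB draw with variance mu + phi * mu**2 (gamma-Poisson mixture)."""
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(config: GeneratorConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the pooled two-genotype single-cell UMI matrix.

    Counts are NB-distributed with mean = base mean x class-marker fold x
    condition multiplier x cell library factor; mitochondrial genes (ids
    prefixed ``mt-``) contribute the configured fraction of each cell's
    expected total.  Identical config and seed give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    M = _class_mean_matrix(config, genes, rng)  # non-mito genes x subclasses
    cmult = _condition_multiplier(genes)

    n = config.n_cells_per_condition
    cond_a, cond_b = config.condition_labels
    conditions = np.array([cond_a] * n + [cond_b] * n, dtype=object)

    props = dict(config.cell_class_proportions)
    class_names = [c for c in CLASSES if props.get(c, 0.0) > 0]
    p = np.array([props[c] for c in class_names])
    cell_class = rng.choice(class_names, size=2 * n, p=p / p.sum())
    is_neuron = cell_class == "neurons"
    gaba = rng.random(2 * n) < config.gaba_fraction
    subclass = cell_class.astype(object).copy()
    subclass[is_neuron & gaba] = "neurons_gaba"
    subclass[is_neuron & ~gaba] = "neurons_glut"
    nt_class = np.array([""] * 2 * n, dtype=object)
    nt_class[is_neuron & gaba] = "GABAergic"
    nt_class[is_neuron & ~gaba] = "glutamatergic"

    sample_no = rng.integers(1, config.n_samples_per_condition + 1, size=2 * n)
    samples = np.array(
        [f"{c}_m{k}" for c, k in zip(conditions, sample_no)], dtype=object
    )
    lib_mu, lib_sigma = config.libsize_lognormal
    lib = rng.lognormal(lib_mu, lib_sigma, size=2 * n)

    sub_idx = {c: i for i, c in enumerate(SUBCLASSES)}
    cls_idx = np.array([sub_idx[c] for c in subclass])
    mu = M[:, cls_idx] * lib[None, :]
    in_b = conditions == cond_b
    mu[:, in_b] *= cmult[:, None]

    # mitochondrial rows: configured fraction of each cell's expected total
    mito_by_class = config._mito_by_class()
    f = np.array([mito_by_class[c] for c in subclass])
    mito_total = f / (1.0 - f) * mu.sum(axis=0)
    w = rng.dirichlet(np.full(len(MITO_GENES), 5.0))
    mu_mito = w[:, None] * mito_total[None, :]

    full_mu = np.vstack([mu, mu_mito])
    counts = _nb_sample(rng, full_mu, config.nb_dispersion)

    # gene table order is non-mito genes then mito genes, matching full_mu
    order = np.concatenate(
        [np.flatnonzero(~genes["is_mito"]), np.flatnonzero(genes["is_mito"])]
    )
    genes = genes.iloc[order].reset_index(drop=True)

    cell_ids = np.array(
        [f"{c}_{i + 1:05d}" for i, c in enumerate(conditions)], dtype=object
    )
    labels = pd.DataFrame(
        {"sample": samples, "condition": conditions}, index=cell_ids
    )
    matrix = CountMatrix(
        sp.csr_matrix(counts.astype(np.int64)),
        genes["gene_id"].to_numpy(),
        cell_ids,
        labels,
    )
    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "condition": conditions,
            "sample": samples,
            "cell_class": cell_class,
            "nt_class": nt_class,
            "subclass": subclass,
            "lib_factor": lib,
            "mito_fraction": f,
        }
    )
    truth_genes = genes.copy()
    truth_genes.loc[truth_genes["is_mito"], "base_mean"] = np.nan
    truth = GroundTruth(truth_cells, truth_genes, config.seed,
                        config.condition_labels)
    return matrix, truth


def simulate_bulk(
    config: GeneratorConfig, n_replicates: int = 5
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the gene x sample bulk experiment (whole-tissue mixture).

    Each sample's expected profile is the class-proportion-weighted mixture
    of the single-cell class means, scaled by ``bulk_depth`` and a lognormal
    per-sample library multiplier recorded in the truth.
    """
    config.validate()
    if n_replicates < 2:
        raise ConfigError(
            "n_replicates must be >= 2 per condition (dispersion unestimable)"
        )
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    M = _class_mean_matrix(config, genes, rng)
    cmult = _condition_multiplier(genes)

    props = dict(config.cell_class_proportions)
    weights = np.zeros(len(SUBCLASSES))
    for i, sub in enumerate(SUBCLASSES):
        if sub == "neurons_gaba":
            weights[i] = props.get("neurons", 0.0) * config.gaba_fraction
        elif sub == "neurons_glut":
            weights[i] = props.get("neurons", 0.0) * (1 - config.gaba_fraction)
        else:
            weights[i] = props.get(sub, 0.0)
    mix = M @ weights  # expected non-mito profile per unit depth

    cond_a, cond_b = config.condition_labels
    conditions = np.array([cond_a] * n_replicates + [cond_b] * n_replicates,
                          dtype=object)
    lib_mu, lib_sigma = config.libsize_lognormal
    lib = rng.lognormal(lib_mu, lib_sigma, size=2 * n_replicates)

    mu = mix[:, None] * lib[None, :] * config.bulk_depth
    mu[:, conditions == cond_b] *= cmult[:, None]

    mito_by_class = config._mito_by_class()
    f_mix = float(np.dot(weights, [mito_by_class[c] for c in SUBCLASSES]))
    mito_total = f_mix / (1.0 - f_mix) * mu.sum(axis=0)
    w = rng.dirichlet(np.full(len(MITO_GENES), 5.0))
    mu_mito = w[:, None] * mito_total[None, :]

    counts = _nb_sample(rng, np.vstack([mu, mu_mito]), config.nb_dispersion_bulk)
    order = np.concatenate(
        [np.flatnonzero(~genes["is_mito"]), np.flatnonzero(genes["is_mito"])]
    )
    genes = genes.iloc[order].reset_index(drop=True)

    sample_ids = np.array(
        [f"{c}_r{i % n_replicates + 1}" for i, c in enumerate(conditions)],
        dtype=object,
    )
    labels = pd.DataFrame(
        {"sample": sample_ids, "condition": conditions}, index=sample_ids
    )
    matrix = CountMatrix(
        sp.csr_matrix(counts.astype(np.int64)),
        genes["gene_id"].to_numpy(),
        sample_ids,
        labels,
    )
    truth_samples = pd.DataFrame(
        {
            "cell_id": sample_ids,
            "condition": conditions,
            "sample": sample_ids,
            "cell_class": "bulk",
            "nt_class": "",
            "subclass": "bulk",
            "lib_factor": lib,
            "mito_fraction": f_mix,
        }
    )
    truth_genes = genes.copy()
    truth_genes.loc[truth_genes["is_mito"], "base_mean"] = np.nan
    truth = GroundTruth(truth_samples, truth_genes, config.seed,
                        config.condition_labels)
    return matrix, truth
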