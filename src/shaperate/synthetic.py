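"""Known-truth synthetic studies: chronogram + landmark specimens + maps.

Every dataset is generated from a serializable :class:`TruthRecord`, so any
downstream estimate can be compared against the parameters that produced the
data, and the whole dataset can be regenerated bit-exactly from the record.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .landmarks import LandmarkConfiguration, write_tps
from .modularity import DEFAULT_PARTITION, ModulePartition
from .trees import Chronogram, read_newick

__all__ = [
    "TruthRecord",
    "BASE_SHAPE_FISH",
    "generate_chronogram",
    "simulate_study",
    "make_fixture",
    "FIXTURES",
]

# 18-landmark fish-like template (x, y), unit-ish body length, left-lateral:
# snout, mouth, jaw, neurocranium, eye ring (4), dorsal fin (2), caudal fin
# (2), anal fin (2), gill/ventral, neurocranium rear, pectoral fin (2).
# Version 1: frozen — tests and fixtures depend on these exact values.
BASE_SHAPE_FISH = np.array(
    [
        [0.00, 0.50],   # 1  anterior tip of snout
        [0.02, 0.44],   # 2  opening of mouth
        [0.10, 0.38],   # 3  posterior edge of jaw
        [0.25, 0.68],   # 4  posterior edge of neurocranium (dorsal)
        [0.13, 0.60],   # 5  upper edge of eye
        [0.17, 0.55],   # 6  posterior edge of eye
        [0.13, 0.50],   # 7  ventral edge of eye
        [0.09, 0.55],   # 8  anterior edge of eye
        [0.55, 0.72],   # 9  anterior edge of dorsal fin
        [0.70, 0.68],   # 10 posterior edge of dorsal fin
        [0.95, 0.62],   # 11 dorsal edge of caudal fin
        [0.95, 0.40],   # 12 ventral edge of caudal fin
        [0.68, 0.36],   # 13 anterior insertion of anal fin
        [0.58, 0.34],   # 14 posterior insertion of anal fin
        [0.22, 0.36],   # 15 gill opening at ventral margin
        [0.27, 0.62],   # 16 posterior-most edge of neurocranium
        [0.28, 0.50],   # 17 upper insertion of pectoral fin
        [0.28, 0.42],   # 18 lower insertion of pectoral fin
    ]
)


@dataclass
class TruthRecord:
    """Everything needed to regenerate a synthetic study bit-exactly."""

    seed: int
    sigma2_by_group: dict[str, float]
    module_rate_multipliers: dict[str, float] = field(default_factory=dict)
    partition: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_PARTITION.modules.items()}
    )
    specimen_noise_sd: float = 0.002
    specimens_per_species: int = 3
    n_clade1: int = 40
    n_clade2: int = 4
    root_age: float = 18.02
    crown_ages: tuple[float, float] = (14.05, 6.88)
    group_labels: tuple[str, str] = ("G", "E")
    base_shape: np.ndarray = field(default_factory=lambda: BASE_SHAPE_FISH.copy())

    def __post_init__(self) -> None:
        self.base_shape = np.asarray(self.base_shape, dtype=float)

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["base_shape"] = self.base_shape.tolist()
        d["partition"] = {k: list(v) for k, v in self.partition.items()}
        d["crown_ages"] = list(self.crown_ages)
        d["group_labels"] = list(self.group_labels)
        return json.dumps(d, sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["base_shape"] = np.asarray(d["base_shape"], dtype=float)
        d["partition"] = {k: tuple(v) for k, v in d["partition"].items()}
        d["crown_ages"] = tuple(d["crown_ages"])
        d["group_labels"] = tuple(d["group_labels"])
        return cls(**d)


def _random_clade_newick(tips: list[str], age: float, rng: np.random.Generator) -> str:
    """Coalescent-style random ultrametric clade with its crown at ``age``.

    n - 1 merge events at sorted uniform times rescaled so the last merge sits
    exactly at the crown age; each event joins two uniformly chosen lineages.
    Merge times are bounded away from zero so terminal branches stay
    non-degenerate (a near-singular covariance is a data pathology, not a
    feature the generator should produce).
    """
    n = len(tips)
    if n == 1:
        return f"{tips[0]}:{age!r}"
    times = np.sort(rng.uniform(0.05, 1.0, size=n - 1))
    times = times * (age / times[-1])
    lineages: list[tuple[str, float]] = [(t, 0.0) for t in tips]
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, ha) = lineages.pop(j)
        (nb, hb) = lineages.pop(i)
        merged = f"({nb}:{float(t - hb)!r},{na}:{float(t - ha)!r})"
        lineages.append((merged, float(t)))
    label, height = lineages[0]
    # the caller appends the stem branch; strip nothing, height == age
    return label[1:-1]  # caller re-wraps with its own parentheses


def generate_chronogram(
    n_clade1: int = 40,
    n_clade2: int = 4,
    root_age: float = 18.02,
    crown_ages: Sequence[float] = (14.05, 6.88),
    seed: int | None = None,
    labels: Sequence[str] = ("G", "E"),
):
    """Two-clade ultrametric chronogram with a seeded random topology.

    Returns ``(tree, group_map)``. Clade crowns sit at the given ages; the
    root split is at ``root_age``. Tips are labeled ``<label><index>``.
    """
    if n_clade1 < 1 or n_clade2 < 1:
        raise ValueError("clade sizes must be >= 1")
    if any(a >= root_age for a in crown_ages):
        raise ValueError("crown ages must be younger than the root age")
    rng = np.random.default_rng(seed)
    parts = []
    group_map: dict[str, str] = {}
    for n, label, crown in zip((n_clade1, n_clade2), labels, crown_ages):
        tips = [f"{label}{i + 1:02d}" for i in range(n)]
        group_map.update({t: label for t in tips})
        if n == 1:
            parts.append(f"{tips[0]}:{root_age!r}")
        else:
            sub = _random_clade_newick(tips, crown, rng)
            parts.append(f"({sub}):{root_age - crown!r}")
    tree = read_newick(f"({parts[0]},{parts[1]});")
    return tree, group_map


def _similarity_tangent_projector(base: np.ndarray) -> np.ndarray:
    """Projector onto the orthogonal complement of translation/rotation/scale
    directions at a centered unit-size base shape (the Procrustes tangent
    frame), acting on vectorized k x 2 configurations."""
    k = base.shape[0]
    b = base - base.mean(axis=0)
    b = b / np.sqrt((b**2).sum())
    u = np.zeros((4, 2 * k))
    u[0, 0::2] = 1.0 / np.sqrt(k)                      # translate x
    u[1, 1::2] = 1.0 / np.sqrt(k)                      # translate y
    u[2] = b.ravel()                                   # scale
    rot = np.column_stack([b[:, 1], -b[:, 0]]).ravel() # infinitesimal rotation
    u[3] = rot / np.linalg.norm(rot)
    return np.eye(2 * k) - u.T @ u


def _simulate_species_deviations(
    tree: Chronogram,
    groups: Mapping[str, str],
    rate_per_column: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Brownian walk down the tree with clade-specific per-column rates.

    The clade of an edge is the clade of the tips below it; every edge in a
    two-clade ultrametric tree (including the two root edges) belongs to
    exactly one clade.
    """
    node_value: dict = {}
    edge_group: dict = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            edge_group[node] = groups[node.taxon.label]
        else:
            child_groups = {edge_group[ch] for ch in node.child_nodes()}
            edge_group[node] = child_groups.pop() if len(child_groups) == 1 else None
    out: dict[str, np.ndarray] = {}
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            node_value[node] = 0.0
            continue
        g = edge_group[node]
        if g is None:
            raise ValueError("edge not assignable to a single clade")
        sd = np.sqrt(rate_per_column[g] * float(node.edge.length))
        node_value[node] = node_value[node.parent_node] + sd * rng.standard_normal(
            len(rate_per_column[g])
        )
        if node.is_leaf():
            out[node.taxon.label] = node_value[node]
    return out


def simulate_study(
    tree: Chronogram,
    groups: Mapping[str, str],
    truth: TruthRecord,
    out_dir: str | os.PathLike | None = None,
):
    """Generate a full synthetic study on an existing chronogram.

    Species mean shapes evolve by Brownian motion from ``truth.base_shape``
    in its Procrustes tangent frame, with clade rates ``sigma2_by_group`` and
    per-module rate multipliers. Specimens add isotropic digitizing noise and
    are then randomly rotated, translated, and scaled before writing, so GPA
    has real work to do.

    Returns ``(configs, species_map, truth)``; when ``out_dir`` is given also
    writes ``specimens.tps``, ``tree.nwk``, ``species_map.csv``,
    ``groups.csv`` and ``truth.json``.
    """
    k = truth.base_shape.shape[0]
    p = 2 * k
    base = truth.base_shape - truth.base_shape.mean(axis=0)
    size = np.sqrt((base**2).sum())
    if size == 0:
        raise ValueError("degenerate base shape")
    base = base / size

    partition = ModulePartition(dict(truth.partition))
    partition.validate_for(k)
    mult = np.ones(p)
    for name, factor in truth.module_rate_multipliers.items():
        if factor < 0:
            raise ValueError("negative module rate multiplier")
        mult[partition.columns(name)] = factor
    rate_per_column = {
        g: sigma2 * mult for g, sigma2 in truth.sigma2_by_group.items()
    }
    missing = sorted(set(groups.values()) - set(rate_per_column))
    if missing:
        raise KeyError(f"groups without a rate: {missing}")

    rng = np.random.default_rng(truth.seed)
    deviations = _simulate_species_deviations(tree, groups, rate_per_column, rng)
    P = _similarity_tangent_projector(base)

    configs: list[LandmarkConfiguration] = []
    species_map: dict[str, str] = {}
    for species in tree.tip_labels:
        mean_vec = base.ravel() + P @ deviations[species]
        mean_shape = mean_vec.reshape(k, 2)
        for j in range(truth.specimens_per_species):
            noisy = mean_shape + truth.specimen_noise_sd * rng.standard_normal((k, 2))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            R = np.array(
                [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
            )
            scale = rng.uniform(50.0, 150.0)
            shift = rng.uniform(-100.0, 100.0, size=2)
            raw = scale * (noisy @ R) + shift
            spec_id = f"{species}_s{j + 1}"
            configs.append(LandmarkConfiguration(spec_id, raw, species_id=species))
            species_map[spec_id] = species

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tps(configs, out / "specimens.tps")
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        with open(out / "species_map.csv", "w") as fh:
            fh.write("specimen,species\n")
            for spec_id, species in species_map.items():
                fh.write(f"{spec_id},{species}\n")
        with open(out / "groups.csv", "w") as fh:
            fh.write("species,group\n")
            for species in tree.tip_labels:
                fh.write(f"{species},{groups[species]}\n")
        (out / "truth.json").write_text(truth.to_json(indent=2) + "\n")
    return configs, species_map, truth


def _tiny_6taxa() -> TruthRecord:
    return TruthRecord(
        seed=20240001,
        sigma2_by_group={"G": 2.0e-5, "E": 1.0e-5},
        specimens_per_species=3,
        n_clade1=4,
        n_clade2=2,
        root_age=18.02,
        crown_ages=(14.05, 6.88),
    )


def _paper_scale_44taxa() -> TruthRecord:
    return TruthRecord(
        seed=20240002,
        sigma2_by_group={"G": 2.0e-5, "E": 1.0e-5},
        specimens_per_species=5,
        n_clade1=40,
        n_clade2=4,
        root_age=18.02,
        crown_ages=(14.05, 6.88),
    )


FIXTURES = {
    "tiny-6taxa": _tiny_6taxa,
    "paper-scale-44taxa": _paper_scale_44taxa,
}


def make_fixture(name: str, out_dir: str | os.PathLike | None = None):
    """Deterministic packaged dataset by name.

    Returns ``(tree, group_map, configs, species_map, truth)``.
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    truth = FIXTURES[name]()
    tree, group_map = generate_chronogram(
        truth.n_clade1,
        truth.n_clade2,
        truth.root_age,
        truth.crown_ages,
        seed=truth.seed,
        labels=truth.group_labels,
    )
    configs, species_map, truth = simulate_study(tree, group_map, truth, out_dir)
    return tree, group_map, configs, species_map, truth
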