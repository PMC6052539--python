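"""End-to-end orchestration: files in, machine-readable study report out.

The pipeline is a pure function of (input files, config, seed): read TPS and
tree, GPA, species means, taxon matching/pruning, the overall clade rate
test, per-module clade tests, the modularity rate test, and morphospace
exports. Stage timings go to logging only; the report contains no clocks, so
identical inputs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landmarks import align_gpa, read_tps, species_means
from .modularity import ModulePartition, DEFAULT_PARTITION, modularity_rate_test, within_module_clade_test
from .morphospace import phylomorphospace
from .rates import rate_ratio_test
from .trees import prune_to, read_newick

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    tree: str
    tps: str
    species_map: str
    group_map: str
    output_dir: str = "shaperate_out"
    partition: dict[str, list[int]] | None = None
    nsim: int = 9999
    seed: int = 0
    tangent: bool = False
    isotropic_null: bool = False
    strict_matching: bool = False

    def __post_init__(self) -> None:
        if self.nsim < 99:
            raise ConfigError("nsim must be >= 99")

    def module_partition(self) -> ModulePartition:
        if self.partition is None:
            return DEFAULT_PARTITION
        return ModulePartition({k: tuple(v) for k, v in self.partition.items()})

    def check_paths(self) -> None:
        for attr in ("tree", "tps", "species_map", "group_map"):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise ConfigError(f"{attr} file does not exist: {path}")


def load_config(path, **overrides) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _read_two_column_csv(path, key: str, value: str) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if key not in df.columns or value not in df.columns:
        raise DataError(f"{path}: expected columns {key!r} and {value!r}")
    return dict(zip(df[key].str.strip(), df[value].str.strip()))


def validate_inputs(config: RunConfig) -> dict[str, Any]:
    """Census of the inputs: counts and unmatched names on both sides."""
    config.check_paths()
    tree = read_newick(Path(config.tree).read_text())
    configs = read_tps(config.tps)
    species_map = _read_two_column_csv(config.species_map, "specimen", "species")
    group_map = _read_two_column_csv(config.group_map, "species", "group")

    specimen_ids = [c.specimen_id for c in configs]
    unmapped_specimens = sorted(s for s in specimen_ids if s not in species_map)
    shape_species = sorted(set(species_map[s] for s in specimen_ids if s in species_map))
    tree_tips = set(tree.tip_labels)
    matched = sorted(tree_tips.intersection(shape_species))
    return {
        "n_specimens": len(configs),
        "n_species_in_shapes": len(shape_species),
        "n_tree_tips": tree.n_tips,
        "n_matched": len(matched),
        "matched": matched,
        "unmatched_in_shapes": sorted(set(shape_species) - tree_tips),
        "unmatched_in_tree": sorted(tree_tips - set(shape_species)),
        "unmapped_specimens": unmapped_specimens,
        "species_without_group": sorted(set(shape_species) - set(group_map)),
    }


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write the report files.

    Returns the report dict; writes ``report.json``, ``rates.csv``,
    ``species_means.csv`` and per-scope morphospace CSV/JSON files under
    ``config.output_dir``.
    """
    census = validate_inputs(config)
    if census["unmapped_specimens"]:
        raise DataError(
            f"specimens without species mapping: {census['unmapped_specimens'][:5]}"
        )
    if census["species_without_group"]:
        raise DataError(
            f"species without group label: {census['species_without_group'][:5]}"
        )
    if census["n_matched"] == 0:
        raise DataError("no taxa shared between tree and shape data")
    if config.strict_matching and (
        census["unmatched_in_shapes"] or census["unmatched_in_tree"]
    ):
        raise DataError(
            "strict matching: unmatched taxa "
            f"(shapes: {census['unmatched_in_shapes']}, tree: {census['unmatched_in_tree']})"
        )

    partition = config.module_partition()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = _stage("read inputs")
    tree = read_newick(Path(config.tree).read_text())
    configs = read_tps(config.tps)
    species_map = _read_two_column_csv(config.species_map, "specimen", "species")
    group_map = _read_two_column_csv(config.group_map, "species", "group")
    logger.info("read inputs done in %.2fs", time.perf_counter() - t0)

    t0 = _stage("generalized Procrustes analysis")
    gpa = align_gpa(configs, tangent=config.tangent)
    logger.info(
        "GPA: %d specimens, %d iterations, converged=%s (%.2fs)",
        len(configs), gpa.iterations, gpa.converged, time.perf_counter() - t0,
    )

    t0 = _stage("species means and taxon matching")
    Y_all = species_means(gpa, species_map)
    matched = census["matched"]
    if len(matched) < 3:
        raise DataError(f"only {len(matched)} matched taxa; need >= 3")
    tree_m = prune_to(tree, matched) if len(matched) < tree.n_tips else tree
    Y = Y_all.reorder(matched)
    logger.info("matched %d taxa (%.2fs)", len(matched), time.perf_counter() - t0)

    partition.validate_for(Y.k)
    seeds = np.random.SeedSequence(config.seed).spawn(3 + len(partition.modules))
    seed_ints = [int(s.generate_state(1)[0]) for s in seeds]

    t0 = _stage("overall clade rate test")
    overall = rate_ratio_test(
        Y, tree_m, group_map, nsim=config.nsim, seed=seed_ints[0],
        isotropic_null=config.isotropic_null,
    )
    logger.info("overall test done (%.2fs)", time.perf_counter() - t0)

    t0 = _stage("within-module clade tests")
    module_tests = {}
    for i, (name, landmarks) in enumerate(sorted(partition.modules.items())):
        module_tests[name] = within_module_clade_test(
            Y, tree_m, group_map, landmarks, nsim=config.nsim,
            seed=seed_ints[1 + i], isotropic_null=config.isotropic_null,
        )
    logger.info("module tests done (%.2fs)", time.perf_counter() - t0)

    t0 = _stage("modularity rate test")
    modularity = modularity_rate_test(
        Y, tree_m, partition, nsim=config.nsim,
        seed=seed_ints[-2], isotropic_null=config.isotropic_null,
    )
    logger.info("modularity test done (%.2fs)", time.perf_counter() - t0)

    t0 = _stage("morphospace")
    spaces = {"overall": phylomorphospace(tree_m, Y)}
    from .landmarks import subset_landmarks

    for name, landmarks in sorted(partition.modules.items()):
        spaces[name] = phylomorphospace(tree_m, subset_landmarks(Y, landmarks))
    logger.info("morphospace done (%.2fs)", time.perf_counter() - t0)

    report = {
        "software": {"name": "shaperate", "version": __version__},
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "census": {
            k: v for k, v in census.items() if k != "matched"
        } | {"n_matched": census["n_matched"]},
        "overall": json.loads(overall.to_json()),
        "modules": {n: json.loads(r.to_json()) for n, r in module_tests.items()},
        "modularity": json.loads(modularity.to_json()),
        "morphospace": {
            n: {
                "variance_explained_pc1": float(s.variance_explained[0]),
                "variance_explained_pc2": float(s.variance_explained[1]),
                "n_tips": len(s.taxa),
                "n_nodes": len(s.node_scores),
            }
            for n, s in spaces.items()
        },
    }

    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n"
    )
    rows = [dict(test="overall", **overall.to_csv_row())]
    rows += [dict(test=f"module:{n}", **r.to_csv_row()) for n, r in module_tests.items()]
    rows.append(dict(test="modularity", **modularity.to_csv_row()))
    pd.DataFrame(rows).to_csv(out / "rates.csv", index=False)
    Y.to_csv(out / "species_means.csv")
    for name, space in spaces.items():
        space.to_csv(out / f"morphospace_{name}.csv")
        (out / f"morphospace_{name}.json").write_text(space.to_json(indent=2) + "\n")
    return report
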