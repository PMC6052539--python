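import numpy as np
import pytest

from shaperate.synthetic import BASE_SHAPE_FISH, _random_clade_newick
from shaperate.trees import read_newick


@pytest.fixture
def cherry_plus_outgroup():
    """((A:1,B:1):1,C:2); — covariance [[2,1,0],[1,2,0],[0,0,2]]."""
    return read_newick("((A:1,B:1):1,C:2);")


def random_chronogram(n_tips: int, age: float, seed: int, prefix: str = "t"):
    """Random ultrametric tree with crown age ``age`` (coalescent-style)."""
    rng = np.random.default_rng(seed)
    tips = [f"{prefix}{i + 1:02d}" for i in range(n_tips)]
    return read_newick(f"({_random_clade_newick(tips, age, rng)});")


def nuisance_copy(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rotation + translation + scaling of a k x 2 configuration."""
    theta = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    return rng.uniform(0.5, 2.0) * (coords @ R) + rng.uniform(-10, 10, size=2)


@pytest.fixture
def base_shape():
    return BASE_SHAPE_FISH.copy()


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """The tiny-6taxa fixture written to disk once per session."""
    from shaperate.synthetic import make_fixture

    out = tmp_path_factory.mktemp("tiny") / "data"
    tree, group_map, configs, species_map, truth = make_fixture("tiny-6taxa", out)
    return {
        "dir": out,
        "tree": tree,
        "group_map": group_map,
        "configs": configs,
        "species_map": species_map,
        "truth": truth,
    }


def write_config(path, data_dir, **overrides):
    """YAML RunConfig pointing at a fixture directory."""
    import yaml

    cfg = {
        "tree": str(data_dir / "tree.nwk"),
        "tps": str(data_dir / "specimens.tps"),
        "species_map": str(data_dir / "species_map.csv"),
        "group_map": str(data_dir / "groups.csv"),
        "output_dir": str(path.parent / "out"),
        "nsim": 199,
        "seed": 7,
    }
    cfg.update(overrides)
    path.write_text(yaml.safe_dump(cfg))
    return path
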