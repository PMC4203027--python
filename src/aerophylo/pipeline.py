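"""End-to-end run: simulate -> transform -> coefficients -> estimate -> code -> map.

A run is fully described by a :class:`RunConfig`; all intermediate tables
are persisted in the output directory and a manifest records the seed, a
hash of the configuration and the package version, so a rerun with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characters import EFFECTIVENESS_THRESHOLD, build_matrix
from .coefficients import ModelGeometry, coefficients_from_moments, reynolds
from .derivatives import DEFAULT_CI_LEVEL, DEFAULT_WINDOW_DEG, estimate_all, estimates_to_frame
from .frames import average_replicates, transform_records
from .parsimony import parsimony_reconstruct, read_nexus, summarize_mapping
from .synthetic import (
    build_test_design,
    make_fixture_suite,
    random_truth,
    simulate_taxon,
    write_records,
)

__all__ = ["RunConfig", "run_pipeline", "demo_config", "DEMO_TREE_NEWICK"]

log = logging.getLogger("aerophylo")

#: eight-tip demo topology: the four reference fixtures plus four random
#: virtual taxa, with a polytomy left unresolved
DEMO_TREE_NEWICK = (
    "((sphere,weathervane),(long_tailed,(virtual_1,virtual_2,"
    "(short_tailed,(virtual_3,virtual_4)))))root;"
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str
    seed: int = 0
    fixtures: bool = True  # include the sphere/weathervane/archetype suite
    n_random_taxa: int = 0
    design: dict = field(default_factory=dict)  # TestDesign overrides
    snout_vent: float = 0.08  # m
    planform_area: float = 0.02  # m^2
    sensor_offset: tuple = (-0.05, 0.0, 0.0)  # m, COM-to-sensor
    kinematic_viscosity: float = 1.5e-5  # m^2 s^-1
    ci_level: float = DEFAULT_CI_LEVEL
    threshold: float = EFFECTIVENESS_THRESHOLD
    window_deg: float = DEFAULT_WINDOW_DEG
    tree_newick: str | None = None  # rooted, tips matching taxa
    named_nodes: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if self.threshold < 0:
            raise ValueError("effectiveness threshold must be >= 0")
        if self.window_deg <= 0:
            raise ValueError("window must be positive")
        if self.n_random_taxa < 0:
            raise ValueError("n_random_taxa must be >= 0")
        if not self.fixtures and self.n_random_taxa == 0:
            raise ValueError("nothing to simulate: no fixtures and no random taxa")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sensor_offset" in raw:
            raw["sensor_offset"] = tuple(raw["sensor_offset"])
        return cls(**raw)


def demo_config(out_dir, seed: int = 0) -> RunConfig:
    """Bundled demonstration: fixtures + 4 random taxa on the 8-tip tree."""
    return RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        fixtures=True,
        n_random_taxa=4,
        tree_newick=DEMO_TREE_NEWICK,
        named_nodes={
            "root": ["sphere", "short_tailed"],
            "calibration": ["sphere", "weathervane"],
            "glider_clade": ["long_tailed", "short_tailed"],
        },
    )


def _stage(name: str, **info):
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Raises at the first failing stage, naming it.  Outputs: ``records.csv``,
    ``moments.csv``, ``moments_mean.csv``, ``coefficients.csv``,
    ``estimates.csv``, ``truth_states.csv`` (when ground truth is known),
    ``matrix.nex`` + ``matrix_discrete.csv`` + ``matrix_continuous.csv``,
    ``mapping.csv``/``mapping.txt`` (when a tree is given) and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    design = build_test_design(config.design)
    _stage("design", positions=len(design.positions()), replicates=design.replicates,
           reynolds=f"{reynolds(design.U, config.snout_vent, config.kinematic_viscosity):.0f}")

    truths, truth_states = {}, {}
    if config.fixtures:
        truths.update(make_fixture_suite())
    for i in range(config.n_random_taxa):
        name = f"virtual_{i + 1}"
        truths[name], truth_states[name] = random_truth(name, rng)
    for name, truth in truths.items():
        truth_states.setdefault(name, truth.character_states(config.threshold))

    geometry = {
        name: ModelGeometry(name, config.snout_vent, config.planform_area,
                            np.asarray(config.sensor_offset, dtype=float))
        for name in truths
    }

    try:
        frames = []
        for name in sorted(truths):
            taxon_seed = int(rng.integers(0, 2**31 - 1))
            frames.append(simulate_taxon(truths[name], design, geometry[name], taxon_seed))
        records = pd.concat(frames, ignore_index=True)
        write_records(records, out / "records.csv")
        _stage("simulate", taxa=len(truths), records=len(records))
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    try:
        moments = transform_records(records)
        moments.to_csv(out / "moments.csv", index=False)
        average_replicates(moments).to_csv(out / "moments_mean.csv", index=False)
        _stage("transform", rows=len(moments))
    except Exception as err:
        raise RuntimeError(f"stage 'transform' failed: {err}") from err

    try:
        coeffs = coefficients_from_moments(moments, geometry)
        coeffs.to_csv(out / "coefficients.csv", index=False)
        _stage("coefficients", rows=len(coeffs))
    except Exception as err:
        raise RuntimeError(f"stage 'coefficients' failed: {err}") from err

    try:
        estimates = estimate_all(coeffs, window_deg=config.window_deg, ci_level=config.ci_level)
        est_frame = estimates_to_frame(estimates)
        est_frame.to_csv(out / "estimates.csv", index=False)
        _stage("estimate", estimates=len(est_frame))
    except Exception as err:
        raise RuntimeError(f"stage 'estimate' failed: {err}") from err

    try:
        matrix, continuous = build_matrix(estimates, threshold=config.threshold)
        matrix.to_nexus(out / "matrix.nex")
        matrix.to_csv(out / "matrix_discrete.csv")
        continuous.to_csv(out / "matrix_continuous.csv", index_label="taxon")
        pd.DataFrame.from_dict(truth_states, orient="index").sort_index().to_csv(
            out / "truth_states.csv", index_label="taxon"
        )
        _stage("code", taxa=len(matrix.taxa), characters=len(matrix.characters))
    except Exception as err:
        raise RuntimeError(f"stage 'code' failed: {err}") from err

    if config.tree_newick:
        try:
            import dendropy

            tree = dendropy.Tree.get(
                data=config.tree_newick, schema="newick", preserve_underscores=True
            )
            tree.is_rooted = True
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            missing = set(matrix.taxa) - tips
            if missing:
                raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
            results = {}
            for label in matrix.characters:
                states = {t: matrix.symbol(t, label) for t in matrix.taxa}
                symbols = ["0", "1", "2"] if label.startswith("stab_") else ["0", "1"]
                results[label] = parsimony_reconstruct(tree, states, symbols, character=label)
            named = config.named_nodes or {"root": sorted(matrix.taxa)[:2]}
            report = summarize_mapping(results, named, tree)
            report.to_csv(out / "mapping.csv", index=False)
            with open(out / "mapping.txt", "w") as fh:
                fh.write(report.to_string(index=False) + "\n")
            _stage("map", characters=len(results), nodes=len(named))
        except Exception as err:
            raise RuntimeError(f"stage 'map' failed: {err}") from err

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "taxa": sorted(truths),
        "n_records": int(len(records)),
        "n_estimates": int(len(est_frame)),
        "characters": list(matrix.characters),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def configure_logging(verbose: bool = False, logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(message)s",
        handlers=handlers,
        force=True,
    )
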