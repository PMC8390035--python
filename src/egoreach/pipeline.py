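"""End-to-end orchestration: read or generate microdata, select the target
population, build both networks, classify, grade vulnerability, tabulate,
and write every output plus a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .networks import Definition, build_network, networks_long, networks_wide
from .schema import (
    RadiusPolicy,
    read_microdata,
    select_target_population,
    write_microdata,
)
from .synthetic import GeneratorParams, generate_population
from .tables import (
    roles_distribution,
    size_by_role,
    type_by_covariate,
    type_distribution,
    vulnerability_by_metro,
)
from .typology import per_ego_results

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("egoreach")

_COVARIATES = ("territorial_area", "place_of_residence", "education")


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (real microdata) or ``params`` (synthetic
    generation) must be set.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    input_path: Optional[Path] = None
    schema_config: Optional[Path] = None
    params: Optional[GeneratorParams] = None
    radius_policy: RadiusPolicy = RadiusPolicy.SAME_MUNICIPALITY
    definitions: tuple[Definition, ...] = (Definition.EASY, Definition.ACCUSTOMED)
    group_keys: tuple[str, ...] = ("age_group", "living_arrangement", "gender")
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.input_path is None) == (self.params is None):
            raise ValueError("set exactly one of input_path or params")
        if not self.definitions:
            raise ValueError("at least one network definition is required")
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk).

    Identical (config, seed) produce byte-identical outputs: the only source
    of randomness is the seeded generator, and all writers are deterministic.
    """
    logging.basicConfig(level=config.log_level.upper())
    out = Path(config.out_dir)
    tables_dir = out / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)

    if config.params is not None:
        logger.info("generating synthetic population (seed=%d)", config.seed)
        frame = generate_population(config.params, seed=config.seed)
        source = {"kind": "synthetic", "params_digest": config.params.digest()}
    else:
        logger.info("reading microdata from %s", config.input_path)
        frame = read_microdata(config.input_path, config.schema_config)
        source = {
            "kind": "real",
            "input_path": str(config.input_path),
            "input_sha256": _sha256(Path(config.input_path)),
        }

    frame = select_target_population(frame)
    logger.info("target population: %d egos", len(frame))

    write_microdata(frame, out / "population.csv")

    results = per_ego_results(frame, config.definitions, config.radius_policy)
    results.to_csv(out / "per_ego_results.csv", index=False)

    nets = [
        build_network(rec, d, config.radius_policy)
        for rec in frame
        for d in config.definitions
    ]
    networks_wide(nets).to_csv(out / "networks_wide.csv", index=False)
    networks_long(nets).to_csv(out / "networks_long.csv", index=False)

    written: dict[str, str] = {}
    for d in config.definitions:
        dv = Definition(d).value
        roles_distribution(results, config.group_keys, d).to_csv(
            tables_dir / f"roles_distribution_{dv}.csv"
        )
        size_by_role(results, config.group_keys, d).to_csv(tables_dir / f"size_by_role_{dv}.csv")
        type_distribution(results, config.group_keys, d).to_csv(
            tables_dir / f"type_distribution_{dv}.csv"
        )
        for cov in _COVARIATES:
            type_by_covariate(results, cov, d).to_csv(tables_dir / f"types_by_{cov}_{dv}.csv")
    if set(config.definitions) == {Definition.EASY, Definition.ACCUSTOMED}:
        vulnerability_by_metro(results).to_csv(tables_dir / "vulnerability_by_metro.csv")

    for path in sorted(out.rglob("*.csv")):
        written[str(path.relative_to(out))] = _sha256(path)

    manifest = {
        "egoreach_version": __version__,
        "seed": config.seed,
        "radius_policy": config.radius_policy.value,
        "definitions": [Definition(d).value for d in config.definitions],
        "group_keys": list(config.group_keys),
        "source": source,
        "n_egos": len(frame),
        "neighbor_count_rule": "presence contributes 1 alter when the count is unknown",
        "sd_denominator": "sample (n-1)",
        "outputs": written,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d output files to %s", len(written) + 1, out)
    return manifest
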