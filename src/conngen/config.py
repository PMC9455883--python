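"""JSON network configuration: schema, generation driver, provenance.

A config declares populations (sizes, roles, optional spatial layout),
projections (rule + parameters + autapse/multapse policy + optional weight
and delay parameterization), and a mandatory seed.  Each projection draws
from its own deterministically derived RNG substream (projection index ->
spawn key), so adding a projection never perturbs the edges of earlier
ones.  ``run_generate`` writes one edge-list TSV per projection plus a JSON
provenance record from which the exact same files can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from importlib import metadata
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import Constraints, EdgeList, Population, Role, derive_rng, logger
from .deterministic import connect_all_to_all, connect_explicit, connect_one_to_one
from .io import write_edge_list_tsv
from .probabilistic import RuleSpec, generate
from .spatial import Profile, Space, connect_spatial_bernoulli, place_grid, place_uniform

__all__ = [
    "PopulationSpec", "ProjectionSpec", "SpaceSpec", "ParamSpec",
    "NetworkConfig", "load_config", "build_network", "run_generate",
    "regenerate",
]

SUPPORTED_RULES = (
    "one_to_one", "all_to_all", "explicit",
    "pairwise_bernoulli", "fixed_total", "fixed_in", "fixed_out",
    "spatial_bernoulli",
)
DETERMINISTIC_RULES = ("one_to_one", "all_to_all", "explicit")


class SpaceSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dimension: int = 2
    extent: list[float] = Field(default_factory=lambda: [1.0, 1.0])
    metric: Literal["euclidean", "maxnorm"] = "euclidean"
    boundary: Literal["periodic", "open"] = "periodic"

    def to_space(self) -> Space:
        return Space(self.dimension, tuple(self.extent), self.metric, self.boundary)


class LayoutSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["uniform", "grid"] = "uniform"
    jitter: float = 0.0
    shape: Optional[list[int]] = None


class PopulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    size: int = Field(ge=1)
    role: Literal["generic", "excitatory", "inhibitory",
                  "stimulator", "recorder"] = "generic"
    layout: Optional[LayoutSpec] = None


class ParamSpec(BaseModel):
    """Weight or delay parameterization: constant or distributed."""

    model_config = ConfigDict(extra="forbid")
    kind: Literal["constant", "distributed"] = "constant"
    value: Optional[float] = None
    distribution: Optional[str] = None  # e.g. "normal", "lognormal"
    params: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ParamSpec":
        if self.kind == "constant" and self.value is None:
            raise ValueError("constant parameter needs 'value'")
        if self.kind == "distributed" and not self.distribution:
            raise ValueError("distributed parameter needs 'distribution'")
        return self


class ProfileSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str
    params: dict[str, Any] = Field(default_factory=dict)

    def to_profile(self) -> Profile:
        return Profile(self.kind, dict(self.params))


class ProjectionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: Optional[str] = None
    source: str
    target: str
    rule: str
    p: Optional[float] = None
    n_syn: Optional[int] = None
    k_in: Optional[int] = None
    k_out: Optional[int] = None
    pairs: Optional[list[list[int]]] = None
    profile: Optional[ProfileSpec] = None
    source_perm: Optional[list[int]] = None
    target_perm: Optional[list[int]] = None
    autapses: Optional[bool] = None
    multapses: Optional[bool] = None
    weight: Optional[ParamSpec] = None
    delay: Optional[ParamSpec] = None
    bidirectional: bool = False

    @model_validator(mode="after")
    def _check_rule(self) -> "ProjectionSpec":
        if self.rule not in SUPPORTED_RULES:
            raise ValueError(f"unknown rule {self.rule!r}; supported rules: "
                             f"{', '.join(SUPPORTED_RULES)}")
        needs = {"pairwise_bernoulli": "p", "fixed_total": "n_syn",
                 "fixed_in": "k_in", "fixed_out": "k_out",
                 "explicit": "pairs", "spatial_bernoulli": "profile"}
        req = needs.get(self.rule)
        if req is not None and getattr(self, req) is None:
            raise ValueError(f"rule {self.rule!r} requires field {req!r}")
        return self

    def label(self, index: int) -> str:
        return self.name or f"{index:02d}_{self.source}_to_{self.target}"

    def constraints(self, same_pop: bool) -> Constraints:
        autapses = self.autapses
        if autapses is None:
            if same_pop:
                logger.warning(
                    "projection %s->%s: autapse policy not specified; defaulting "
                    "to disallowed — set 'autapses' explicitly in configs",
                    self.source, self.target)
            autapses = False
        multapses = False if self.multapses is None else self.multapses
        return Constraints(allow_autapses=autapses, allow_multapses=multapses)


class NetworkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    populations: list[PopulationSpec]
    projections: list[ProjectionSpec]
    space: Optional[SpaceSpec] = None
    seed: int = Field(ge=0, description="mandatory root seed")

    @model_validator(mode="after")
    def _check_refs(self) -> "NetworkConfig":
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for proj in self.projections:
            for ref in (proj.source, proj.target):
                if ref not in names:
                    raise ValueError(f"projection references unknown population {ref!r}")
        if any(p.layout is not None for p in self.populations) and self.space is None:
            raise ValueError("populations declare layouts but no space is given")
        return self

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(exclude_none=True), sort_keys=True,
                          separators=(",", ":"))

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def load_config(path: str | Path) -> NetworkConfig:
    """Parse and schema-validate a JSON config file.

    A missing seed is rejected: seeds are mandatory for reproducibility.
    """
    with Path(path).open() as fh:
        data = json.load(fh)
    if "seed" not in data:
        raise ValueError(f"{path}: config must set 'seed' (mandatory for "
                         "reproducibility)")
    return NetworkConfig.model_validate(data)


def build_network(
    config: NetworkConfig,
) -> tuple[dict[str, Population], list[tuple[ProjectionSpec, EdgeList]]]:
    """Instantiate populations (with layouts) and all projection edge lists."""
    space = config.space.to_space() if config.space else None
    pops: dict[str, Population] = {}
    offset = 0
    for i, spec in enumerate(config.populations):
        positions = None
        if spec.layout is not None:
            rng = derive_rng(config.seed, stream=1000 + i)
            if spec.layout.kind == "uniform":
                positions = place_uniform(space, spec.size, rng)
            else:
                shape = tuple(spec.layout.shape) if spec.layout.shape else None
                positions = place_grid(space, spec.size, spec.layout.jitter,
                                       rng, shape=shape)
        pops[spec.name] = Population(spec.name, spec.size, offset=offset,
                                     role=Role(spec.role), positions=positions)
        offset += spec.size

    results: list[tuple[ProjectionSpec, EdgeList]] = []
    for k, proj in enumerate(config.projections):
        src, tgt = pops[proj.source], pops[proj.target]
        same = proj.source == proj.target
        cons = proj.constraints(same)
        rng = derive_rng(config.seed, stream=k)
        if proj.rule == "one_to_one":
            edges = connect_one_to_one(src, tgt, proj.source_perm, proj.target_perm)
        elif proj.rule == "all_to_all":
            edges = connect_all_to_all(src, tgt, cons)
        elif proj.rule == "explicit":
            edges = connect_explicit([tuple(p) for p in proj.pairs], src, tgt)
        elif proj.rule == "spatial_bernoulli":
            edges = connect_spatial_bernoulli(src, tgt, space,
                                              proj.profile.to_profile(), cons, rng)
        else:
            rule = RuleSpec(variant=proj.rule, p=proj.p, n_syn=proj.n_syn,
                            k_in=proj.k_in, k_out=proj.k_out, constraints=cons)
            edges = generate(rule, src, tgt, rng)
        results.append((proj, edges))
    return pops, results


def _package_version() -> str:
    try:
        return metadata.version("conngen")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_generate(config: NetworkConfig, out_dir: str | Path) -> dict:
    """Generate all projections, write TSVs and a provenance record.

    The provenance JSON embeds the full config, its hash, the seed, the
    package version, and per-projection edge counts — enough to regenerate
    every output byte-for-byte with :func:`regenerate`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pops, results = build_network(config)
    record: dict = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.hash(),
        "seed": config.seed,
        "conngen_version": _package_version(),
        "projections": [],
    }
    for k, (proj, edges) in enumerate(results):
        label = proj.label(k)
        fname = f"{label}.tsv"
        weights = delays = None
        if proj.weight is not None and proj.weight.kind == "constant":
            weights = proj.weight.value
            if proj.delay is not None and proj.delay.kind == "constant":
                delays = proj.delay.value
        write_edge_list_tsv(out / fname, edges, weights=weights, delays=delays)
        record["projections"].append({
            "name": label, "file": fname, "n_syn": len(edges),
            "rule": proj.rule,
        })
        logger.info("projection %s: rule=%s N_syn=%d", label, proj.rule, len(edges))
    with (out / "provenance.json").open("w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return record


def regenerate(provenance: dict, out_dir: str | Path) -> dict:
    """Re-run generation from a provenance record (byte-identical outputs)."""
    config = NetworkConfig.model_validate(provenance["config"])
    if config.hash() != provenance["config_hash"]:
        raise ValueError("provenance config hash mismatch")
    return run_generate(config, out_dir)
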