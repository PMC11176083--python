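"""Run configuration: YAML round-trip and deterministic seed fan-out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .filtering import FilterConfig
from .simulate import DriverSite, SimParams

__all__ = ["RunConfig", "stage_seed", "STAGES"]

STAGES = ("simulate", "filter", "dnds", "fitness", "classify")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage child seed: SeedSequence(global_seed, spawn_key=(stage index,)).

    Stages are therefore independently reproducible from the single top-level
    seed; the derived value is folded to < 2**31.
    """
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, round-trippable through YAML."""

    seed: int = 0
    out_dir: str = "runs/out"
    n_genes: int = 50
    gene_length_codons: tuple[int, int] = (120, 400)
    splice_sites_per_gene: int = 0
    sim: SimParams = field(default_factory=SimParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    # (s, mu) pairs: stage_simulate assigns each to the first missense site of
    # the i-th generated gene, so a config file needs no sequence knowledge
    auto_drivers: tuple[tuple[float, float], ...] = ()
    dnds_q_threshold: float = 0.1
    fitness_top_k: int = 10
    fitness_f_min: float = 0.11
    classify_canonical_genes: tuple[str, ...] = ()
    classify_pinned_driverless_count: int | None = None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"]["driver_sites"] = [list(x) for x in (
            (s.gene_id, s.cds_pos, s.ref, s.alt, s.s, s.mu) for s in self.sim.driver_sites
        )]
        d["filter"]["gene_blacklist"] = sorted(self.filter.gene_blacklist)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim_d = d.pop("sim", {})
        drivers = tuple(
            DriverSite(g, int(p), r, a, float(s), float(m))
            for g, p, r, a, s, m in sim_d.pop("driver_sites", [])
        )
        filt_d = d.pop("filter", {})
        filt_d["gene_blacklist"] = frozenset(filt_d.get("gene_blacklist", ()))
        known = {f.name for f in fields(cls)}
        cfg = cls(
            sim=SimParams(driver_sites=drivers, **sim_d),
            filter=FilterConfig(**filt_d),
            **{k: v for k, v in d.items() if k in known},
        )
        if isinstance(cfg.gene_length_codons, list):
            cfg.gene_length_codons = tuple(cfg.gene_length_codons)
        if isinstance(cfg.classify_canonical_genes, list):
            cfg.classify_canonical_genes = tuple(cfg.classify_canonical_genes)
        cfg.auto_drivers = tuple(tuple(x) for x in cfg.auto_drivers)
        return cfg
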