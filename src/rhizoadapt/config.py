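"""Run configuration: a flat key-value file (YAML syntax) with documented
defaults. Unknown keys warn rather than error; every missing key falls back
to its default and the resolved configuration is echoed into the output
bundle."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "rhizoadapt_out"

    # experiment 1 design
    n_genotypes: int = 40
    n_replicates: int = 5
    n_blocks: int = 5
    spatial_range_km: float = 300.0
    n_loci: int = 20
    ibd_strength: float = 1.0

    # community stage
    rarefaction_depth_16s: int = 9000
    rarefaction_depth_nifh: int = 3600
    unifrac_normalized: bool = False

    # inference stage
    n_permutations: int = 999
    selection_permutations: int = 199
    alpha: float = 0.05
    condition_on: str = "geo,ssr"    # comma-set of {geo, ssr}
    mem_subset: str = "broad"        # 'broad' (eigenvalue > mean) or 'all'

    # experiment 2 / microbial effect
    n_genotypes_subset: int = 10
    n_replicates_expt2: int = 10
    n_simulations: int = 10000
    mc_draws: int = 10000
    propagation: str = "montecarlo"  # or "delta"

    def __post_init__(self):
        if self.n_permutations < 99 or self.selection_permutations < 99:
            raise ValueError("permutation counts must be >= 99")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.propagation not in ("montecarlo", "delta"):
            raise ValueError("propagation must be 'montecarlo' or 'delta'")
        if self.mem_subset not in ("broad", "all"):
            raise ValueError("mem_subset must be 'broad' or 'all'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key: value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}",
                          stacklevel=2)
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_dict(self) -> dict:
        return asdict(self)

    def conditions(self) -> list[str]:
        toks = [t.strip() for t in self.condition_on.split(",") if t.strip()]
        bad = set(toks) - {"geo", "ssr"}
        if bad:
            raise ValueError(f"unknown condition source(s): {sorted(bad)}")
        return toks
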