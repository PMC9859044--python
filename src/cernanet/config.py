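"""Pipeline-wide thresholds and switches.

Every tunable number used by the filtering cascade, the DE screen, target
prediction and network assembly lives here so a run is fully described by
one config object (plus the RNG seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, FrozenSet

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for the full lncRNA / DE / target / network pipeline.

    Attributes
    ----------
    fdr_threshold : float
        BH-adjusted significance cutoff for differential expression.
    abs_fc_threshold : float
        Minimum |fold change| (linear scale) for a DE call.
    min_exons : int
        Minimum exon count for an lncRNA candidate.
    min_tx_length : int
        Minimum spliced transcript length in nt (length > 200 means 201).
    fpkm_floor : float
        Minimum FPKM required in at least one sample (inclusive).
    domain_evalue_max : float
        Protein-domain hits with E-value strictly below this discard a
        transcript from the noncoding set.
    cis_window_bp : int
        Maximum genomic distance (bp, inclusive) for cis target pairing.
    trans_abs_rho_min : float
        Trans pairs require |Spearman rho| strictly above this value.
    trans_p_max : float
        Trans pairs require correlation p-value strictly below this.
    enrich_p_max : float
        Raw hypergeometric p cutoff for enrichment significance.
    hub_top_n : int
        Size of the PPI degree hub ranking (ties at the cut all kept).
    class_codes_kept : frozenset of str
        Assembly class codes retained by the first cascade stage.
    rng_seed : int
        Seed for every stochastic component.
    """

    fdr_threshold: float = 0.05
    abs_fc_threshold: float = 2.0
    min_exons: int = 2
    min_tx_length: int = 201
    fpkm_floor: float = 0.1
    domain_evalue_max: float = 1e-5
    cis_window_bp: int = 100_000
    trans_abs_rho_min: float = 0.8
    trans_p_max: float = 0.05
    enrich_p_max: float = 0.05
    hub_top_n: int = 10
    class_codes_kept: FrozenSet[str] = frozenset({"i", "u", "x"})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "fdr_threshold",
            "abs_fc_threshold",
            "min_exons",
            "min_tx_length",
            "fpkm_floor",
            "domain_evalue_max",
            "cis_window_bp",
            "trans_abs_rho_min",
            "trans_p_max",
            "enrich_p_max",
            "hub_top_n",
        ]
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.class_codes_kept:
            raise ValueError("class_codes_kept must be non-empty")

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        if "class_codes_kept" in kwargs:
            kwargs["class_codes_kept"] = frozenset(kwargs["class_codes_kept"])
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_codes_kept"] = sorted(self.class_codes_kept)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "class_codes_kept" in d:
            d["class_codes_kept"] = frozenset(d["class_codes_kept"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML (or JSON; YAML is a superset) mapping."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
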