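"""Run configuration: every pipeline threshold in one validated object.

Defaults are the thresholds conventional for giant-virus pangenome
annotation: 50-aa minimum ORF length; clustering at 30% identity / 50%
coverage; reciprocal-hit orthology at 30% identity / 70% coverage; homology
significance at e ≤ 1e−3 with 30% query coverage for the ORFan call; ≥ 10
mapped reads to call an ORF transcribed; MITE size bounds 100–600 bp. The
resolved configuration is echoed verbatim into every output directory so a
run is reproducible from its artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulateParams:
    n_genomes: int = 6
    n_core: int = 50
    n_shell: int = 30
    shell_p: float = 0.5
    n_cloud_per_genome: int = 20
    identity: float = 0.8
    paralog_prob: float = 0.05


@dataclass
class RunConfig:
    min_orf_len: int = 50
    cluster_id: float = 0.30
    cluster_cov: float = 0.50
    cluster_cov_mode: str = "shorter"
    brh_id_pct: float = 30.0
    brh_cov: float = 0.70
    brh_cov_mode: str = "both"
    e_max: float = 1e-3
    orfan_q_cov: float = 0.30
    orfan_cov_source: str = "best"
    read_min: int = 10
    mite_min_len: int = 100
    mite_max_len: int = 600
    mite_min_query_cov: float = 0.90
    openness_threshold_pct: float = 5.0
    seed: int = 0
    run_brh: bool = False
    proteome_fastas: list[str] = field(default_factory=list)
    genome_lengths: dict[str, int] = field(default_factory=dict)
    outdir: str = "pandorapan_out"
    simulate: SimulateParams = field(default_factory=SimulateParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, v in (
            ("cluster_id", self.cluster_id),
            ("cluster_cov", self.cluster_cov),
            ("brh_cov", self.brh_cov),
            ("orfan_q_cov", self.orfan_q_cov),
            ("mite_min_query_cov", self.mite_min_query_cov),
        ):
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if not 0.0 <= self.brh_id_pct <= 100.0:
            raise ValueError("brh_id_pct must be a percentage in [0, 100]")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.min_orf_len < 1 or self.read_min < 0:
            raise ValueError("min_orf_len must be >= 1 and read_min >= 0")
        if not 0 < self.mite_min_len <= self.mite_max_len:
            raise ValueError("invalid MITE size bounds")
        if self.cluster_cov_mode not in ("shorter", "both"):
            raise ValueError("cluster_cov_mode must be 'shorter' or 'both'")
        if self.brh_cov_mode not in ("both", "query"):
            raise ValueError("brh_cov_mode must be 'both' or 'query'")
        if self.orfan_cov_source not in ("best", "any", "union"):
            raise ValueError("orfan_cov_source must be 'best', 'any' or 'union'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulate", {})
        cfg = cls(**data, simulate=SimulateParams(**sim) if isinstance(sim, dict) else sim)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
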