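"""Run configuration: one serializable record of every knob a run used."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run; written beside every output set.

    Thresholds carry the pipeline's defaults: primer matching (<=2
    mismatches, exact 3' pentamer), the gap-PCR extension ceiling (2 kb vs
    25 kb for long-range PCR), het-site floors (depth 20, minor fraction
    0.20, minor count 5), the structural-variant size floor (50 bp) and
    junction support floor (3 reads).
    """

    seed: int = 0
    # error model (amplicon reads)
    substitution_rate: float = 0.02
    insertion_rate: float = 0.015
    deletion_rate: float = 0.025
    read_length_mean: float = 8_000
    read_length_sd: float = 2_000
    # error model (whole-locus reads)
    wgs_error_rate: float = 0.002
    wgs_read_length_mean: float = 12_000
    wgs_read_length_sd: float = 3_000
    # depths
    amplicon_depth: float = 30
    wgs_depth: float = 30
    # primer matching / PCR
    primer_max_mismatches: int = 2
    primer_exact_3prime: int = 5
    gap_pcr_max_product: int = 2_000
    lr_pcr_max_product: int = 25_000
    # het sites / clustering
    het_min_depth: int = 20
    het_min_fraction: float = 0.20
    het_min_count: int = 5
    cluster_min_reads: int = 10
    # SV calling
    min_sv_size: int = 50
    min_sv_support: int = 3
    # cohorts
    n_donors: int = 600
    n_carriers: int = 3
    # misc
    outdir: str = "results/run"
    threads: int = 1  # results are independent of thread count
    verbose: bool = False

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_carriers > self.n_donors:
            raise ValueError("n_carriers cannot exceed n_donors")
        if self.amplicon_depth < 1 or self.wgs_depth < 10:
            raise ValueError("depths below supported floors")
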