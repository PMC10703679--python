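"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives here; stage code
contains no literal cutoffs. Defaults are the published constants of the
protocol this package implements (QC bounds, the 1 kb upstream rescue window,
30 gene + 10 exon principal components, the 1e-5 abundance pseudocount, the
x100,000 log-normalization scale, and so on).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple


@dataclass
class ReadLayout:
    """Positions of barcode components within read 1.

    The combinatorial barcode is split-pool: a ligation index at the start of
    read 1, then the UMI, then the RT index (which encodes sample, well and
    primer class through the whitelist annotation). Read 2 is cDNA. The PCR
    index arrives per-file (demultiplexed upstream by the sequencer), so it is
    a parameter of the demux run, not of the read.
    """

    lig_start: int = 0
    lig_len: int = 10
    umi_start: int = 10
    umi_len: int = 8
    rt_start: int = 18
    rt_len: int = 10

    @property
    def min_read1_len(self) -> int:
        return max(
            self.lig_start + self.lig_len,
            self.umi_start + self.umi_len,
            self.rt_start + self.rt_len,
        )


@dataclass
class PipelineConfig:
    # barcode handling
    max_barcode_mismatch: int = 1
    # read-to-gene assignment
    upstream_rescue_bp: int = 1000
    # cell QC
    qc_max_unassigned_frac: float = 0.30
    qc_max_umis: int = 20000
    qc_min_genes: int = 200
    # subclustering
    n_gene_pcs: int = 30
    n_exon_pcs: int = 10
    # marker / DE selection
    marker_fc_min: float = 2.0
    marker_tpm_min: float = 50.0
    de_fdr: float = 0.05
    human_de_fc_min: float = 1.5
    # differential abundance
    abundance_pseudocount: float = 1e-5
    abundance_fc_min: float = 2.0
    abundance_min_cells_per_sex: int = 20
    abundance_sex_covariate: bool = True
    # normalization
    norm_scale: float = 1e5
    # gene modules
    gm_min_expr: float = 1.0
    gm_min_fc: float = 5.0
    gm_umap_min_dist: float = 0.01
    gm_umap_n_neighbors: int = 30
    gm_rho: float = 1.0
    gm_delta: float = 1.0
    # cis-regulatory linkage
    cre_tpm_min: float = 10.0
    cre_window_bp: int = 500000
    cre_fdr: float = 0.01
    cre_promoter_bp: int = 2000
    cre_n_permutations: int = 1
    # ATAC peak handling
    atac_spm_cutoff: float = 1.3
    atac_summit_pad_bp: int = 250
    atac_diff_tpm_min: float = 20.0
    # TF motif correlation
    motif_rescale_range: Tuple[float, float] = (0.0, 10.0)
    # aging clock
    clock_pseudobulk_k: int = 15
    clock_train_frac: float = 0.8
    # clustering hyperparameters not printed in the protocol, exposed here
    cluster_resolution: float = 1.0
    cluster_n_neighbors: int = 15
    merge_min_sep: float = 1.0
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "qc_max_unassigned_frac",
            "de_fdr",
            "abundance_pseudocount",
            "cre_fdr",
            "clock_train_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "max_barcode_mismatch",
            "upstream_rescue_bp",
            "qc_max_umis",
            "qc_min_genes",
            "n_gene_pcs",
            "n_exon_pcs",
            "abundance_min_cells_per_sex",
            "cre_window_bp",
            "cre_promoter_bp",
            "atac_summit_pad_bp",
            "clock_pseudobulk_k",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    # -- flat key=value persistence ------------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(known[key].type, val.strip())
        return cls(**kwargs)


def _coerce(typ, val: str):
    t = str(typ)
    if "bool" in t:
        return val.lower() in ("1", "true", "yes", "on")
    if "Tuple" in t or "tuple" in t:
        return tuple(float(x) for x in val.split(","))
    if "int" in t:
        return int(val)
    if "float" in t:
        return float(val)
    return val
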