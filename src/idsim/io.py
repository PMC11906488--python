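"""File formats and run provenance.

Genetic maps are tab-delimited HapMap-style tables (physical position bp,
local rate cM/Mb, cumulative cM). Genotype matrices round-trip through
plain-text VCF (1-based positions, GT fields, a contig header carrying the
region length, and a flag recording minor-allele orientation); reading uses
cyvcf2. A RunManifest records scenario name, seed, a configuration hash and
stage outputs so that identical manifests imply identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import GenotypeMatrix
from .simcore import DFEConfig, GeneticMap, ScenarioConfig

__all__ = [
    "read_genetic_map",
    "write_genetic_map",
    "write_vcf",
    "read_vcf",
    "write_genotype_table",
    "write_registry_table",
    "config_hash",
    "RunManifest",
]

_MAP_COLUMNS = ["pos_bp", "rate_cM_per_Mb", "cM"]


def read_genetic_map(path) -> GeneticMap:
    """Read a tab-delimited genetic map (pos bp, rate cM/Mb, cumulative cM)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty genetic map file: {path}")
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genetic map {path} lacks columns {missing}")
    if (df["rate_cM_per_Mb"] < 0).any():
        raise ValueError("negative recombination rate in genetic map")
    pos = df["pos_bp"].to_numpy(dtype=np.float64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("genetic map positions must be strictly ascending")
    return GeneticMap(breakpoints=pos, cum_cM=df["cM"].to_numpy(dtype=np.float64))


def write_genetic_map(gmap: GeneticMap, path) -> None:
    bp = gmap.breakpoints
    cm = gmap.cum_cM
    rate = np.zeros(len(bp))
    rate[:-1] = np.diff(cm) / np.diff(bp) * 1e6
    if len(rate) > 1:
        rate[-1] = rate[-2]
    pd.DataFrame({"pos_bp": bp.astype(np.int64), "rate_cM_per_Mb": rate, "cM": cm}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_CONTIG = "region1"
_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(m: GenotypeMatrix, path, sample_prefix: str = "ind") -> None:
    """Write the matrix as an uncompressed VCF.

    The ALT allele is the minor allele; columns folded at export carry the
    MINOR_IS_WT flag so orientation survives a round trip. Positions are
    1-based in the file (0-based internally).
    """
    path = Path(path)
    samples = [f"{sample_prefix}{i}" for i in range(m.n_individuals)]
    ids = (
        m.mut_id
        if m.mut_id is not None
        else np.full(m.n_snps, -1, dtype=np.int64)
    )
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=idsim {__version__}\n")
        fh.write(f"##contig=<ID={_CONTIG},length={m.region_length}>\n")
        fh.write(
            '##INFO=<ID=MINOR_IS_WT,Number=0,Type=Flag,'
            'Description="Minor allele is the wild-type allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for k in range(m.n_snps):
            info = "MINOR_IS_WT" if m.flipped[k] else "."
            vid = f"mut{ids[k]}" if ids[k] >= 0 else "."
            gts = "\t".join(_GT[int(x)] for x in m.counts[:, k])
            fh.write(
                f"{_CONTIG}\t{int(m.pos[k]) + 1}\t{vid}\tA\tT\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF written by :func:`write_vcf` back into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if _CONTIG not in vcf.seqnames:
        raise ValueError(f"malformed VCF: contig {_CONTIG!r} missing from header")
    region_length = int(dict(zip(vcf.seqnames, vcf.seqlens))[_CONTIG])
    pos, dosage, flipped, ids = [], [], [], []
    for v in vcf:
        pos.append(v.POS - 1)
        dosage.append([a + b for a, b, *_ in v.genotypes])
        flipped.append(bool(v.INFO.get("MINOR_IS_WT")))
        ids.append(int(v.ID[3:]) if v.ID and v.ID.startswith("mut") else -1)
    counts = np.asarray(dosage, dtype=np.int8).T
    p = counts.mean(axis=0) / 2.0
    return GenotypeMatrix(
        counts=counts,
        p=p,
        pos=np.asarray(pos, dtype=np.int64),
        region_length=region_length,
        flipped=np.asarray(flipped, dtype=bool),
        mut_id=np.asarray(ids, dtype=np.int64),
    )


def write_genotype_table(m: GenotypeMatrix, path) -> None:
    """Plain tab-delimited dosage matrix (SNPs as columns named by position)."""
    df = pd.DataFrame(
        m.counts, columns=[f"pos{int(p)}" for p in m.pos]
    )
    df.insert(0, "individual", np.arange(m.n_individuals))
    df.to_csv(path, sep="\t", index=False)


def write_registry_table(registry: pd.DataFrame, path) -> None:
    registry.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def config_hash(cfg: ScenarioConfig, dfe: DFEConfig) -> str:
    """Stable hash of the full configuration (region map included)."""
    doc = {
        "scenario": {
            **{
                k: v
                for k, v in cfg.__dict__.items()
                if k not in ("region", "seed")
            },
            "region": {
                "length_bp": cfg.region.length_bp,
                "breakpoints": cfg.region.map.breakpoints.tolist(),
                "cum_cM": cfg.region.map.cum_cM.tolist(),
            },
        },
        "dfe": dataclasses.asdict(dfe),
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    scenario: str
    seed: int | None
    config_hash: str
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
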