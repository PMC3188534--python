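"""Readers and writers for the standard formats the pipeline touches.

Internally all coordinates are 0-based, half-open.  Emitted formats use
their native conventions: VCF and PED/MAP are 1-based, BED is 0-based
half-open.  The simulated chromosome is always labelled "1".
"""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import MISSING, GenotypePanel
from .popsim import DiploidPopulation

__all__ = [
    "write_ped_map", "read_ped_map",
    "write_vcf", "read_vcf",
    "write_bed", "write_segments_tsv", "write_mask_rle",
    "write_table", "stage_seed", "config_hash",
    "load_config", "save_config",
]

CHROM = "1"


# ---------------------------------------------------------------- PED/MAP
def write_ped_map(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write PLINK text PED/MAP; missing genotypes become "0 0"."""
    prefix = Path(prefix)
    map_df = pd.DataFrame({
        "chr": CHROM,
        "snp": panel.snp_ids,
        "cm": panel.cm,
        "bp": panel.positions + 1,  # 1-based
    })
    map_df.to_csv(prefix.with_suffix(".map"), sep="\t", header=False,
                  index=False)
    ref, alt = panel.ref, panel.alt
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(panel.n_individuals):
            g = panel.genotypes[i]
            a1 = np.where(g == MISSING, "0", np.where(g >= 1, alt, ref))
            a2 = np.where(g == MISSING, "0", np.where(g == 2, alt, ref))
            cells = np.empty(2 * g.size, dtype=a1.dtype)
            cells[0::2], cells[1::2] = a1, a2
            fid = str(panel.sample_ids[i])
            fh.write(" ".join([fid, fid, "0", "0", "0", "-9", *cells]) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypePanel:
    """Read PLINK text PED/MAP back into a genotype panel.

    Allele letters carry no ref/alt designation in PED, so the
    lexicographically smaller observed allele is taken as reference -- the
    convention :func:`write_ped_map` sorted its labels to satisfy.
    """
    prefix = Path(prefix)
    map_df = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                         names=["chr", "snp", "cm", "bp"])
    m = len(map_df)
    genotypes = []
    sample_ids = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix.with_suffix('.ped')}: line {lineno} has "
                    f"{len(fields)} fields, expected {6 + 2 * m}")
            sample_ids.append(fields[1])
            genotypes.append(fields[6:])
    alleles = np.asarray(genotypes).reshape(len(genotypes), m, 2)
    ref = np.empty(m, dtype="U1")
    alt = np.empty(m, dtype="U1")
    codes = np.empty((len(genotypes), m), dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        seen = np.unique(col[col != "0"])
        if seen.size > 2:
            raise ValueError(f"SNP {map_df['snp'][j]}: more than two alleles")
        ref[j] = seen[0] if seen.size else "A"
        alt[j] = seen[1] if seen.size > 1 else ref[j]
        dose = (col == alt[j]).sum(axis=1).astype(np.int8) if seen.size > 1 \
            else np.zeros(len(genotypes), dtype=np.int8)
        dose[(col == "0").any(axis=1)] = MISSING
        codes[:, j] = dose
    return GenotypePanel(
        genotypes=codes,
        positions=map_df["bp"].to_numpy(np.int64) - 1,
        cm=map_df["cm"].to_numpy(float),
        ref=ref, alt=alt,
        snp_ids=map_df["snp"].to_numpy(str),
        sample_ids=np.asarray(sample_ids),
    )


# -------------------------------------------------------------------- VCF
_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rohbench
##contig=<ID={chrom},length={length}>
##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position in cM">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(obj: GenotypePanel | DiploidPopulation, path: str | Path) -> None:
    """Write GT-only VCF 4.2: phased for sequence haplotypes, unphased for
    array genotypes."""
    path = Path(path)
    if isinstance(obj, DiploidPopulation):
        _write_vcf_population(obj, path)
    else:
        _write_vcf_panel(obj, path)


def _write_vcf_panel(panel: GenotypePanel, path: Path) -> None:
    length = panel.region_length or int(panel.positions[-1] + 1) \
        if panel.n_snps else 1
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=CHROM, length=length))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.sample_ids)) + "\n")
        for j in range(panel.n_snps):
            gts = "\t".join(_GT_UNPHASED[int(g)] for g in panel.genotypes[:, j])
            fh.write(f"{CHROM}\t{panel.positions[j] + 1}\t{panel.snp_ids[j]}\t"
                     f"{panel.ref[j]}\t{panel.alt[j]}\t.\t.\t"
                     f"CM={panel.cm[j]:.6f}\tGT\t{gts}\n")


def _write_vcf_population(pop: DiploidPopulation, path: Path) -> None:
    cm = pop.cm
    h = pop.haplotypes
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=CHROM, length=pop.region_length))
        samples = "\t".join(f"ind{i}" for i in range(pop.n_individuals))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + samples + "\n")
        for j in range(pop.n_variants):
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}"
                            for i in range(pop.n_individuals))
            fh.write(f"{CHROM}\t{pop.positions[j] + 1}\tv{pop.positions[j]}\t"
                     f"A\tG\t.\t.\tCM={cm[j]:.6f}\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a GT-only VCF into a genotype panel (biallelic records only)."""
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples)
    positions, cms, refs, alts, ids, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record at POS {rec.POS}",
                          stacklevel=2)
            continue
        positions.append(rec.POS - 1)
        cm = rec.INFO.get("CM")
        cms.append(float(cm) if cm is not None else np.nan)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ids.append(rec.ID if rec.ID else f"snp{rec.POS - 1}")
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        rows.append(np.select(
            [rec.gt_types == 0, rec.gt_types == 1, rec.gt_types == 3],
            [0, 1, 2], default=MISSING).astype(np.int8))
    vcf.close()
    m = len(positions)
    genotypes = (np.stack(rows, axis=1) if m else
                 np.zeros((sample_ids.size, 0), dtype=np.int8))
    cm_arr = np.asarray(cms)
    if np.isnan(cm_arr).any():
        cm_arr = np.nan_to_num(cm_arr)
    return GenotypePanel(genotypes=genotypes,
                         positions=np.asarray(positions, dtype=np.int64),
                         cm=cm_arr, ref=np.asarray(refs), alt=np.asarray(alts),
                         snp_ids=np.asarray(ids), sample_ids=sample_ids)


# ------------------------------------------------------------ segments etc
def write_bed(segments: pd.DataFrame, path: str | Path) -> None:
    """Write segment intervals as BED (0-based half-open); expects columns
    individual, start_bp, end_bp."""
    df = segments[["start_bp", "end_bp", "individual"]].copy()
    df.insert(0, "chrom", CHROM)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_segments_tsv(segments: pd.DataFrame, path: str | Path,
                       header_comment: str | None = None) -> None:
    write_table(segments, path, header_comment)


def write_mask_rle(mask: np.ndarray, path: str | Path) -> None:
    """Per-variant boolean mask as run-length text: one line per individual,
    comma-separated (value, length) pairs."""
    with open(path, "w") as fh:
        for row in np.asarray(mask, dtype=np.int8):
            if not row.size:
                fh.write("\n")
                continue
            change = np.flatnonzero(np.diff(row)) + 1
            bounds = np.concatenate([[0], change, [row.size]])
            parts = [f"{row[b]}x{bounds[k + 1] - b}"
                     for k, b in enumerate(bounds[:-1])]
            fh.write(",".join(parts) + "\n")


def write_table(df: pd.DataFrame, path: str | Path,
                header_comment: str | None = None) -> None:
    """TSV with an optional '# ...' provenance header line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ------------------------------------------------------------------ config
def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a global seed."""
    ss = np.random.SeedSequence([int(global_seed),
                                 zlib.crc32(stage.encode("utf8"))])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha1(canon.encode("utf8")).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
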