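"""VCF v4.2 and tabular I/O.

Internal coordinates are 0-based half-open; the VCF boundary converts to
1-based.  Only biallelic SNP records with a GT field are consumed;
multiallelic records are skipped and counted.  Written VCFs carry the
effect category as ``INFO/EFFECT`` and round-trip exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_HAP_STR = {0: "0", 1: "1", MISSING: "."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=urbanpurge"]
    for c in dict.fromkeys(gm.chrom):
        length = gm.chrom_lengths.get(c)
        if length is None:
            length = int(gm.pos[gm.chrom == c].max()) + 1
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append(
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Site effect category">'
    )
    lines.append(
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [str(s) for s in gm.samples]
    lines.append("\t".join(header))
    gt_map = _GT_STR if gm.ploidy == 2 else _HAP_STR
    for k in range(gm.n_sites):
        aa = "A" if gm.ancestral_is_ref[k] else "T"
        info = f"EFFECT={gm.effect[k]};AA={aa}"
        row = [
            str(gm.chrom[k]),
            str(int(gm.pos[k]) + 1),
            ".",
            "A",
            "T",
            ".",
            "PASS",
            info,
            "GT",
        ]
        row += [gt_map[int(g)] for g in gm.genotypes[k]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_vcf(
    path, pops: dict[str, str] | None = None, ref_is_ancestral: bool = True
) -> GenotypeMatrix:
    """Read biallelic SNP records into a :class:`GenotypeMatrix`.

    ``pops`` maps sample id -> population label (default: single
    population ``"pop0"``).  Effect categories come from ``INFO/EFFECT``
    when present, else ``"intergenic"``.  Returns the matrix; the number
    of skipped multiallelic records is available as
    ``gm.n_multiallelic_skipped``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom_lengths = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            fields = line.split("<", 1)[1].rstrip(">").split(",")
            kv = dict(f.split("=", 1) for f in fields if "=" in f)
            if "ID" in kv and "length" in kv:
                chrom_lengths[kv["ID"]] = int(kv["length"])
    geno, chroms, poss, effects, anc = [], [], [], [], []
    n_multi = 0
    ploidy = None
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        row = []
        for g in var.genotypes:
            alleles = [a for a in g[:-1] if a != -1]
            p = len(g) - 1
            if ploidy is None:
                ploidy = p
            elif p != ploidy:
                raise ValueError("mixed ploidy across records/samples")
            if len(alleles) < p:
                row.append(MISSING)
            else:
                row.append(sum(alleles))
        geno.append(row)
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        effects.append(var.INFO.get("EFFECT") or "intergenic")
        aa = var.INFO.get("AA")
        anc.append(ref_is_ancestral if aa is None else (aa == var.REF))
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic records", n_multi)
    pop_labels = [pops.get(s, "pop0") if pops else "pop0" for s in samples]
    gm = GenotypeMatrix(
        genotypes=np.array(geno, dtype=np.int8)
        if geno
        else np.empty((0, len(samples)), dtype=np.int8),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        effect=np.array(effects, dtype=object),
        pop=np.array(pop_labels, dtype=object),
        samples=np.array(samples, dtype=object),
        ancestral_is_ref=np.array(anc, dtype=bool),
        ploidy=ploidy or 2,
        chrom_lengths=chrom_lengths,
    )
    gm.n_multiallelic_skipped = n_multi
    return gm


def read_pops(path) -> dict[str, str]:
    """Two-column TSV (sample, population) without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"])
    return dict(zip(df["sample"].astype(str), df["pop"].astype(str)))


def read_effects(path) -> pd.DataFrame:
    """TSV of per-site effect categories: chrom, pos (1-based), effect."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "effect"])
    df["pos"] = df["pos"].astype(int) - 1
    return df


def apply_effects(gm: GenotypeMatrix, effects: pd.DataFrame) -> GenotypeMatrix:
    lookup = {
        (c, p): e for c, p, e in zip(effects["chrom"], effects["pos"], effects["effect"])
    }
    new = np.array(
        [lookup.get((c, int(p)), e) for c, p, e in zip(gm.chrom, gm.pos, gm.effect)],
        dtype=object,
    )
    gm.effect = new
    return gm


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_effects_tsv(gm: GenotypeMatrix, path) -> None:
    pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.pos + 1, "effect": gm.effect}
    ).to_csv(path, sep="\t", header=False, index=False)
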