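"""Readers and writers for the formats the pipeline touches.

Genotypes come in as VCF 4.x (biallelic SNP records, ancestral allele in the
``AA`` INFO tag) or as a tab-separated genotype table with columns
``pos ref alt aa <sample> ...`` and genotype tokens like ``0/1``, ``0|1`` or
``./.``.  Sample metadata is a TSV with columns
``sample population group lat lon``.  All report output is TSV or JSON.
"""

from __future__ import annotations

import json
import os
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import MANIFEST_COLUMNS, GenotypeMatrix, SampleManifest

__all__ = [
    "read_genotype_data",
    "read_manifest",
    "write_manifest",
    "write_genotype_vcf",
    "write_genotype_tsv",
    "write_report_tables",
    "population_origins",
]


def read_manifest(path: str) -> SampleManifest:
    table = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str, "group": str})
    return SampleManifest(table[MANIFEST_COLUMNS])


def write_manifest(manifest: SampleManifest, path: str) -> str:
    manifest.table.to_csv(path, sep="\t", index=False)
    return path


def population_origins() -> pd.DataFrame:
    """Editable table of population origin coordinates shipped with the package."""
    with resources.files("sfspipe").joinpath("data/population_origins.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def read_genotype_data(path: str, manifest_path: str,
                       region_length: int | None = None) -> tuple[GenotypeMatrix, SampleManifest]:
    """Read a genotype file (VCF or TSV, chosen by extension) plus its manifest.

    Every sample column must appear in the manifest; the first offender is
    named in the error.  Ancestral alleles default to '.' when unannotated.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    manifest = read_manifest(manifest_path)
    if path.endswith((".vcf", ".vcf.gz")):
        matrix = _read_vcf(path, region_length)
    else:
        matrix = _read_tsv(path, region_length)
    matrix = _polarity_from_annotation(matrix)
    known = set(manifest.samples)
    for s in matrix.samples:
        if s not in known:
            raise ValueError(f"sample {s!r} in genotype file is absent from the manifest")
    return matrix, manifest


def _polarity_from_annotation(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Set derived-allele flags when every site's ancestral annotation matches
    one of its alleles; otherwise leave the matrix unpolarized (run the QC
    polarization step)."""
    if matrix.n_sites == 0:
        return matrix
    derived = np.zeros(matrix.n_sites, dtype=bool)
    for s in range(matrix.n_sites):
        aa = matrix.ancestral[s]
        if aa == matrix.ref[s]:
            derived[s] = True
        elif aa != matrix.alt[s].split(",")[0]:
            return matrix
    from dataclasses import replace
    return replace(matrix, derived_is_alt=derived,
                   polarization=np.array(["outgroup"] * matrix.n_sites, dtype=object))


def _read_vcf(path: str, region_length: int | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    positions, refs, alts, aas = [], [], [], []
    geno_rows, hap_rows = [], []
    region = None
    contig_len = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            inner = line[line.index("<") + 1:line.rindex(">")]
            fields = dict(kv.split("=", 1) for kv in inner.split(","))
            region = fields.get("ID", region)
            if "length" in fields:
                contig_len = int(fields["length"])
    all_phased = True
    any_site = False
    for var in vcf:
        any_site = True
        region = region or var.CHROM
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(",".join(var.ALT) if var.ALT else ".")
        aa = var.INFO.get("AA")
        aas.append(aa if aa else ".")
        row = np.full(len(samples), -1, dtype=np.int8)
        hap = np.full(2 * len(samples), -1, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b, phased = g[0], g[1], bool(g[2])
            if a < 0 or b < 0:
                continue      # missing cells carry no phase information
            if a > 1 or b > 1:       # third allele: park as missing, site stays flagged via alt
                row[i] = -1
                all_phased = phased and all_phased
                continue
            row[i] = a + b
            hap[2 * i], hap[2 * i + 1] = a, b
            all_phased = phased and all_phased
        geno_rows.append(row)
        hap_rows.append(hap)
    if not any_site:
        raise ValueError(f"no variant records in {path}")
    geno = np.array(geno_rows, dtype=np.int8)
    L = region_length or contig_len or int(max(positions))
    phased = all_phased
    haps = np.array(hap_rows, dtype=np.int8) if phased else None
    return GenotypeMatrix(
        region=region or "region", region_length=L,
        positions=np.array(positions), ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object), ancestral=np.array(aas, dtype=object),
        genotypes=geno, samples=samples, phased=phased, haplotypes=haps,
    )


def _parse_gt(token: str, line_no: int) -> tuple[int, int, bool]:
    sep = "|" if "|" in token else "/"
    parts = token.split(sep)
    if len(parts) != 2:
        raise ValueError(f"malformed genotype {token!r} on line {line_no}")
    out = []
    for p in parts:
        if p == ".":
            out.append(-1)
        elif p in ("0", "1", "2", "3"):
            out.append(int(p))
        else:
            raise ValueError(f"malformed genotype {token!r} on line {line_no}")
    return out[0], out[1], sep == "|"


def _read_tsv(path: str, region_length: int | None) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["pos", "ref", "alt", "aa"]:
            raise ValueError("genotype TSV must start with columns pos ref alt aa")
        samples = header[4:]
        positions, refs, alts, aas, rows, haps = [], [], [], [], [], []
        all_phased = True
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4 + len(samples):
                raise ValueError(f"wrong column count on line {line_no}")
            positions.append(int(parts[0]))
            refs.append(parts[1])
            alts.append(parts[2])
            aas.append(parts[3])
            row = np.full(len(samples), -1, dtype=np.int8)
            hap = np.full(2 * len(samples), -1, dtype=np.int8)
            for i, tok in enumerate(parts[4:]):
                a, b, ph = _parse_gt(tok, line_no)
                all_phased = all_phased and ph
                if a < 0 or b < 0:
                    continue
                if a > 1 or b > 1:
                    continue
                row[i] = a + b
                hap[2 * i], hap[2 * i + 1] = a, b
            rows.append(row)
            haps.append(hap)
    L = region_length or int(max(positions))
    geno = np.array(rows, dtype=np.int8)
    return GenotypeMatrix(
        region=os.path.basename(path).rsplit(".", 1)[0], region_length=L,
        positions=np.array(positions), ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object), ancestral=np.array(aas, dtype=object),
        genotypes=geno, samples=samples, phased=all_phased,
        haplotypes=np.array(haps, dtype=np.int8) if all_phased else None,
    )


def _gt_token(code: int, hap: tuple[int, int] | None, phased: bool) -> str:
    sep = "|" if phased else "/"
    if code < 0:
        return f".{sep}."
    if hap is not None:
        return f"{hap[0]}{sep}{hap[1]}"
    return {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[code]


def write_genotype_vcf(matrix: GenotypeMatrix, path: str) -> str:
    """Write a plain-text VCF 4.2 with AA INFO and a contig line carrying L."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={matrix.region},length={matrix.region_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for s in range(matrix.n_sites):
            info = f"AA={matrix.ancestral[s]}"
            toks = []
            for i in range(matrix.n_samples):
                hap = None
                if matrix.phased and matrix.haplotypes is not None:
                    h0, h1 = matrix.haplotypes[s, 2 * i], matrix.haplotypes[s, 2 * i + 1]
                    if h0 >= 0 and h1 >= 0:
                        hap = (int(h0), int(h1))
                toks.append(_gt_token(int(matrix.genotypes[s, i]), hap, matrix.phased))
            fh.write(f"{matrix.region}\t{matrix.positions[s]}\t.\t{matrix.ref[s]}\t"
                     f"{matrix.alt[s]}\t.\tPASS\t{info}\tGT\t" + "\t".join(toks) + "\n")
    return path


def write_genotype_tsv(matrix: GenotypeMatrix, path: str) -> str:
    with open(path, "w") as fh:
        fh.write("pos\tref\talt\taa\t" + "\t".join(matrix.samples) + "\n")
        for s in range(matrix.n_sites):
            toks = []
            for i in range(matrix.n_samples):
                hap = None
                if matrix.phased and matrix.haplotypes is not None:
                    h0, h1 = matrix.haplotypes[s, 2 * i], matrix.haplotypes[s, 2 * i + 1]
                    if h0 >= 0 and h1 >= 0:
                        hap = (int(h0), int(h1))
                toks.append(_gt_token(int(matrix.genotypes[s, i]), hap, matrix.phased))
            fh.write(f"{matrix.positions[s]}\t{matrix.ref[s]}\t{matrix.alt[s]}\t"
                     f"{matrix.ancestral[s]}\t" + "\t".join(toks) + "\n")
    return path


# ---------------------------------------------------------------------------
# report tables


def _fmt_ci(est: float, lo: float, hi: float, scale: float = 1e5) -> str:
    return f"{est * scale:.2f} ({lo * scale:.2f}-{hi * scale:.2f})"


def write_report_tables(out_dir: str,
                        diversity: pd.DataFrame | None = None,
                        distance_matrices: dict[str, Any] | None = None,
                        fit_results: dict[str, Any] | None = None) -> list[str]:
    """Emit the standard report set: per-unit diversity, pairwise distance
    matrices, per-parameter fit tables with CIs, and a JSON fit summary.

    Returns the list of paths written.  An unwritable directory is a hard
    error from the OS layer.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir!r} is not writable")
    paths: list[str] = []
    if diversity is not None:
        p = os.path.join(out_dir, "diversity.tsv")
        diversity.to_csv(p, sep="\t", index=False)
        paths.append(p)
    for name, dm in (distance_matrices or {}).items():
        p = os.path.join(out_dir, f"{name}.tsv")
        frame = dm.to_frame() if hasattr(dm, "to_frame") else pd.DataFrame(dm)
        frame.to_csv(p, sep="\t")
        paths.append(p)
    summary = {}
    for name, fit in (fit_results or {}).items():
        p = os.path.join(out_dir, f"fit_{name}.tsv")
        fit.to_table().to_csv(p, sep="\t", index=False)
        paths.append(p)
        summary[name] = fit.to_dict()
    if fit_results is not None:
        p = os.path.join(out_dir, "fit_summary.json")
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        paths.append(p)
    return paths


def diversity_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble diversity rows into the fixed-schema report table."""
    cols = ["unit", "level", "nInd", "S", "Sp", "theta", "pi", "H", "HapHet", "TajimaD", "P"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = []
    for r in rows:
        out.append({
            "unit": r["unit"], "level": r["level"], "nInd": r["nInd"],
            "S": r["S"], "Sp": r["Sp"],
            "theta": _fmt_ci(r["theta"], r["theta_lo"], r["theta_hi"]),
            "pi": _fmt_ci(r["pi"], r["pi_lo"], r["pi_hi"]),
            "H": f"{r['H'] * 1e5:.2f}",
            "HapHet": "" if r.get("hap_het") is None else f"{r['hap_het']:.2f}",
            "TajimaD": "" if r.get("tajima_d") is None else f"{r['tajima_d']:.2f}",
            "P": "" if r.get("tajima_p") is None else f"{r['tajima_p']:.2f}",
        })
    return pd.DataFrame(out, columns=cols)
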