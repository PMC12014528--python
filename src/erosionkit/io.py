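"""Readers and writers for the standard formats touched by the pipeline.

Text formats only: BEAGLE genotype-likelihood tables, minimal VCF v4.2
(GT), PLINK PED/MAP, epoch-tagged FASTA, FAI-style scaffold-length tables,
PLINK-.hom-like ROH tables, and a JSON run manifest carrying full seed
provenance. Coordinates are 1-based inclusive everywhere. Readers reject
malformed input rather than guessing.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .gl import BASES, BASE_INDEX, GenotypeLikelihoods
from .rohscan import FROHProfile, ROHSegment
from .simdata import GenotypeData, MtRecord, TruthTable


# ---------------------------------------------------------------------------
# BEAGLE genotype likelihoods
# ---------------------------------------------------------------------------

def write_beagle_gl(gls: GenotypeLikelihoods, path: str | Path) -> None:
    """BEAGLE-style GL text: marker, allele codes, linear triplets per individual."""
    path = Path(path)
    lin = gls.linear()
    with path.open("w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for s in gls.samples:
            cols.extend([s] * 3)
        fh.write("\t".join(cols) + "\n")
        for s_idx, marker in enumerate(gls.markers):
            vals = [marker, str(int(gls.major[s_idx])), str(int(gls.minor[s_idx]))]
            for i in range(gls.n_individuals):
                vals.extend(f"{v:.6g}" for v in lin[s_idx, i])
            fh.write("\t".join(vals) + "\n")


def read_beagle_gl(path: str | Path) -> GenotypeLikelihoods:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise ValueError(f"{path}: malformed BEAGLE header ({len(header)} columns)")
        samples = header[3::3]
        n_ind = len(samples)
        scaffolds, positions, major, minor, trips = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + 3 * n_ind:
                raise ValueError(
                    f"{path}: row {lineno} has {len(parts)} columns, "
                    f"expected {3 + 3 * n_ind}"
                )
            marker = parts[0]
            scaf, _, pos = marker.rpartition("_")
            if not scaf or not pos.isdigit():
                raise ValueError(f"{path}: row {lineno} has malformed marker {marker!r}")
            scaffolds.append(scaf)
            positions.append(int(pos))
            major.append(int(parts[1]))
            minor.append(int(parts[2]))
            try:
                trips.append([float(x) for x in parts[3:]])
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    lin = np.array(trips).reshape(len(trips), n_ind, 3)
    lin = np.maximum(lin, 1e-300)
    ll = np.log(lin)
    ll -= ll.max(axis=2, keepdims=True)
    return GenotypeLikelihoods(
        scaffolds=np.array(scaffolds, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        major=np.array(major, dtype=np.int8),
        minor=np.array(minor, dtype=np.int8),
        loglik=ll,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeData, path: str | Path, seed: int | None = None) -> None:
    """Minimal VCF v4.2 with GT only."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=erosionkit {__version__}\n")
        if seed is not None:
            fh.write(f"##erosionkit_seed={seed}\n")
        for name, length in geno.scaffold_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for s in range(geno.n_sites):
            row = [
                str(geno.scaffolds[s]), str(int(geno.positions[s])), ".",
                BASES[geno.ref[s]], BASES[geno.alt[s]], ".", ".", ".", "GT",
            ]
            row.extend(gt_strings[int(g)] for g in geno.genotypes[:, s])
            fh.write("\t".join(row) + "\n")


def read_vcf_genotypes(
    path: str | Path,
    samples: list[str] | None = None,
    excluded_scaffolds: tuple[str, ...] = (),
) -> GenotypeData:
    """Read biallelic SNP genotypes from a VCF (GT field) via cyvcf2.

    Multi-allelic and non-SNP records are skipped; missing genotypes are -1;
    records on excluded scaffolds are dropped.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path), gts012=True, samples=samples)
    kept_samples = list(vcf.samples)
    excluded = set(excluded_scaffolds)
    scaffold_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig="):
            body = line.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(","))
            if "ID" in fields and "length" in fields:
                scaffold_lengths[fields["ID"]] = int(fields["length"])
    scafs, poss, refs, alts, gts = [], [], [], [], []
    record_no = 0
    try:
        for v in vcf:
            record_no += 1
            if v.CHROM in excluded:
                continue
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue
            if v.REF not in BASE_INDEX or v.ALT[0] not in BASE_INDEX:
                continue
            scafs.append(v.CHROM)
            poss.append(v.POS)
            refs.append(BASE_INDEX[v.REF])
            alts.append(BASE_INDEX[v.ALT[0]])
            g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            g[g == 3] = -1
            gts.append(g)
    except Exception as exc:  # cyvcf2 raises plain Exceptions on bad records
        raise ValueError(f"{path}: malformed VCF at or near record {record_no + 1}: {exc}")
    genotypes = (
        np.array(gts, dtype=np.int8).T
        if gts
        else np.zeros((len(kept_samples), 0), dtype=np.int8)
    )
    return GenotypeData(
        scaffolds=np.array(scafs, dtype=object),
        positions=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=np.int8),
        alt=np.array(alts, dtype=np.int8),
        genotypes=genotypes,
        samples=kept_samples,
        epochs=["unknown"] * len(kept_samples),
        scaffold_lengths=scaffold_lengths,
    )


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def write_ped_map(geno: GenotypeData, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with map_path.open("w") as fh:
        for s in range(geno.n_sites):
            fh.write(f"{geno.scaffolds[s]}\t{geno.scaffolds[s]}_{geno.positions[s]}"
                     f"\t0\t{int(geno.positions[s])}\n")
    with ped_path.open("w") as fh:
        for i, sample in enumerate(geno.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for s in range(geno.n_sites):
                g = int(geno.genotypes[i, s])
                r, a = BASES[geno.ref[s]], BASES[geno.alt[s]]
                pair = {0: (r, r), 1: (r, a), 2: (a, a), -1: ("0", "0")}[g]
                fields.extend(pair)
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path) -> GenotypeData:
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    sites = []
    with map_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{map_path}: line {lineno} has {len(parts)} fields")
            sites.append((parts[0], int(parts[3])))
    n_sites = len(sites)
    samples, rows = [], []
    with ped_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_sites:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * n_sites}"
                )
            samples.append(parts[1])
            rows.append(parts[6:])
    # infer ref/alt per site from observed alleles (ref = most common)
    genotypes = np.full((len(samples), n_sites), -1, dtype=np.int8)
    refs = np.zeros(n_sites, dtype=np.int8)
    alts = np.zeros(n_sites, dtype=np.int8)
    allele_arr = np.array(rows, dtype=object).reshape(len(samples), n_sites, 2)
    for s in range(n_sites):
        pair = allele_arr[:, s, :]
        seen = [a for a in pair.ravel() if a != "0"]
        uniq = sorted(set(seen), key=lambda a: (-seen.count(a), a))
        if not uniq:
            continue
        ref = uniq[0]
        alt = uniq[1] if len(uniq) > 1 else next(b for b in BASES if b != ref)
        refs[s] = BASE_INDEX.get(ref, 0)
        alts[s] = BASE_INDEX.get(alt, 0)
        for i in range(len(samples)):
            a1, a2 = pair[i]
            if a1 == "0" or a2 == "0":
                genotypes[i, s] = -1
            else:
                genotypes[i, s] = (a1 == alt) + (a2 == alt)
    scaffolds = np.array([s for s, _ in sites], dtype=object)
    positions = np.array([p for _, p in sites], dtype=np.int64)
    lengths = {str(s): int(positions[scaffolds == s].max()) for s in set(scaffolds)}
    return GenotypeData(
        scaffolds=scaffolds,
        positions=positions,
        ref=refs,
        alt=alts,
        genotypes=genotypes,
        samples=samples,
        epochs=["unknown"] * len(samples),
        scaffold_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# FASTA with epoch/population tags
# ---------------------------------------------------------------------------

def write_mt_fasta(records: list[MtRecord], path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.name}|epoch={r.epoch}|pop={r.pop}",
            description=f"seed={seed}" if seed is not None else "",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_mt_fasta(path: str | Path) -> list[MtRecord]:
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        name = parts[0]
        tags = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        records.append(
            MtRecord(name, tags.get("epoch", "unknown"), tags.get("pop", "unknown"),
                     str(rec.seq).upper())
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# FAI-style scaffold lengths, truth table, ROH tables
# ---------------------------------------------------------------------------

def write_fai(scaffold_lengths: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, length in scaffold_lengths.items():
            fh.write(f"{name}\t{length}\n")


def read_fai(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno} has fewer than 2 columns")
            lengths[parts[0]] = int(parts[1])
    return lengths


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def roh_table(profiles: list[FROHProfile]) -> pd.DataFrame:
    """PLINK-.hom-like segment table: IID, CHR, POS1, POS2, NSNP, KB."""
    rows = []
    for prof in profiles:
        for seg in prof.segments:
            rows.append(
                {
                    "IID": prof.individual,
                    "CHR": seg.scaffold,
                    "POS1": seg.start,
                    "POS2": seg.end,
                    "NSNP": seg.n_snps,
                    "KB": seg.length / 1000,
                }
            )
    return pd.DataFrame(rows, columns=["IID", "CHR", "POS1", "POS2", "NSNP", "KB"])


def froh_table(profiles: list[FROHProfile]) -> pd.DataFrame:
    rows = []
    for prof in profiles:
        row = {"individual": prof.individual, "froh": prof.froh,
               "denominator_bp": prof.denominator_bp}
        for cls, v in prof.froh_by_class.items():
            row[f"froh_{cls}Mb"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance for one pipeline run: config, seeds, inputs, version."""

    command: str
    config: dict
    seeds: dict[str, int]
    input_checksums: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def utc_now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()
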