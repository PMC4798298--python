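"""File formats for every pipeline artifact.

All tabular artifacts are headered TSV; nested artifacts (rule sets, truth
records, run summaries) are JSON.  Coordinates are 1-based inclusive on disk
and 0-based half-open in memory; :func:`to_disk_interval` and
:func:`from_disk_interval` convert between the two, and single positions
shift by one.  Readers fail loudly: a 0-byte file, a missing column or a
malformed row (reported with its line number) raises ``ValueError``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ALLELE_CODES, ALLELE_NAMES, BY, S3, CrossDesign, GenomeMap
from .hmm import MISSING
from .simulate import PoolCounts, SiteObservations

_STATE_CHARS = {BY: "B", S3: "S", MISSING: "N"}
_STATE_CODES = {"B": BY, "S": S3, "N": MISSING}


# ---------------------------------------------------------------------------
# Coordinate conversion


def to_disk_pos(pos0: int) -> int:
    """0-based in-memory position -> 1-based on-disk position."""
    return int(pos0) + 1


def from_disk_pos(pos1: int) -> int:
    """1-based on-disk position -> 0-based in-memory position."""
    pos1 = int(pos1)
    if pos1 < 1:
        raise ValueError(f"on-disk positions are 1-based; got {pos1}")
    return pos1 - 1


def to_disk_interval(start0: int, end0: int) -> tuple:
    """Half-open 0-based interval -> closed 1-based interval."""
    return int(start0) + 1, int(end0)


def from_disk_interval(start1: int, end1: int) -> tuple:
    """Closed 1-based interval -> half-open 0-based interval."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"bad 1-based interval [{start1}, {end1}]")
    return int(start1) - 1, int(end1)


# ---------------------------------------------------------------------------
# Low-level strict TSV reading


def _read_rows(path, columns):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[: len(columns)] != list(columns):
            raise ValueError(f"{path}: expected header {list(columns)}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0] == ""):
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            yield lineno, row


def _parse_int(value, path, lineno, what):
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: {what} must be an integer, got {value!r}") from None


# ---------------------------------------------------------------------------
# Genome map + design


def write_genome_map(gmap: GenomeMap, map_path, chrom_path):
    with open(chrom_path, "w") as fh:
        fh.write("chromosome\tlength\n")
        for name, length in gmap.chromosomes:
            fh.write(f"{name}\t{length}\n")
    with open(map_path, "w") as fh:
        fh.write("chromosome\tposition\n")
        for ci, pos in zip(gmap.snp_chrom, gmap.snp_pos):
            fh.write(f"{gmap.chrom_names[ci]}\t{to_disk_pos(pos)}\n")


def read_genome_map(map_path, chrom_path, map_scale: float = 3300.0) -> GenomeMap:
    chroms = []
    for lineno, row in _read_rows(chrom_path, ("chromosome", "length")):
        chroms.append((row[0], _parse_int(row[1], chrom_path, lineno, "length")))
    names = [n for n, _ in chroms]
    chrom_idx, pos = [], []
    for lineno, row in _read_rows(map_path, ("chromosome", "position")):
        if row[0] not in names:
            raise ValueError(f"{map_path}:{lineno}: unknown chromosome {row[0]!r}")
        chrom_idx.append(names.index(row[0]))
        pos.append(from_disk_pos(_parse_int(row[1], map_path, lineno, "position")))
    return GenomeMap(tuple(chroms), np.array(chrom_idx), np.array(pos), map_scale)


def write_cross_design(design: CrossDesign, path):
    gmap = design.genome_map
    with open(path, "w") as fh:
        fh.write(f"#backcross_to={design.backcross_to}\n")
        for name, snp in sorted(design.locus_snp.items()):
            fh.write(f"#locus={name}:{snp}\n")
        fh.write("chromosome\tposition\tfocal_allele\n")
        for ci, pos, allele in zip(gmap.snp_chrom, gmap.snp_pos, design.focal_parent):
            fh.write(f"{gmap.chrom_names[ci]}\t{to_disk_pos(pos)}\t{ALLELE_NAMES[int(allele)]}\n")


def read_cross_design(path, gmap: GenomeMap) -> CrossDesign:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    backcross_to = None
    locus_snp = {}
    focal = np.empty(gmap.n_snps, dtype=np.int8)
    seen = 0
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if line.startswith("#backcross_to="):
                backcross_to = line.split("=", 1)[1]
                continue
            if line.startswith("#locus="):
                name, snp = line.split("=", 1)[1].split(":")
                locus_snp[name] = int(snp)
                continue
            if not header_seen:
                if line.split("\t") != ["chromosome", "position", "focal_allele"]:
                    raise ValueError(f"{path}:{lineno}: bad header")
                header_seen = True
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 or fields[2] not in ALLELE_CODES:
                raise ValueError(f"{path}:{lineno}: malformed design row {line!r}")
            snp = gmap.snp_index(fields[0], from_disk_pos(_parse_int(fields[1], path, lineno, "position")))
            focal[snp] = ALLELE_CODES[fields[2]]
            seen += 1
    if backcross_to is None:
        raise ValueError(f"{path}: missing #backcross_to header")
    if seen != gmap.n_snps:
        raise ValueError(f"{path}: design covers {seen} SNPs, map has {gmap.n_snps}")
    return CrossDesign(gmap, focal, backcross_to, locus_snp)


# ---------------------------------------------------------------------------
# Pool counts / observations / genotypes


def write_pool_counts(counts: PoolCounts, gmap: GenomeMap, path):
    idx = counts.indices()
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\tcount_BY\tcount_3S\n")
        for i, cb, cs in zip(idx, counts.count_by, counts.count_3s):
            fh.write(
                f"{gmap.chrom_names[gmap.snp_chrom[i]]}\t{to_disk_pos(gmap.snp_pos[i])}\t{cb}\t{cs}\n"
            )


def read_pool_counts(path, gmap: GenomeMap) -> PoolCounts:
    idx, cb, cs = [], [], []
    for lineno, row in _read_rows(path, ("chromosome", "position", "count_BY", "count_3S")):
        pos0 = from_disk_pos(_parse_int(row[1], path, lineno, "position"))
        try:
            idx.append(gmap.snp_index(row[0], pos0))
        except (KeyError, ValueError):
            raise ValueError(f"{path}:{lineno}: unknown SNP {row[0]}:{row[1]}") from None
        cb.append(_parse_int(row[2], path, lineno, "count_BY"))
        cs.append(_parse_int(row[3], path, lineno, "count_3S"))
    return PoolCounts(np.array(cb), np.array(cs), np.array(idx))


def write_observations(obs_by_individual: dict, gmap: GenomeMap, path):
    """``obs_by_individual``: id -> SiteObservations."""
    with open(path, "w") as fh:
        fh.write("individual\tchromosome\tposition\tcount_BY\tcount_3S\n")
        for ind, obs in obs_by_individual.items():
            for i, cb, cs in zip(obs.snp_index, obs.count_by, obs.count_3s):
                fh.write(
                    f"{ind}\t{gmap.chrom_names[gmap.snp_chrom[i]]}\t{to_disk_pos(gmap.snp_pos[i])}\t{cb}\t{cs}\n"
                )


def read_observations(path, gmap: GenomeMap) -> dict:
    per_ind = {}
    for lineno, row in _read_rows(path, ("individual", "chromosome", "position", "count_BY", "count_3S")):
        pos0 = from_disk_pos(_parse_int(row[2], path, lineno, "position"))
        try:
            snp = gmap.snp_index(row[1], pos0)
        except (KeyError, ValueError):
            raise ValueError(f"{path}:{lineno}: unknown SNP {row[1]}:{row[2]}") from None
        rec = per_ind.setdefault(row[0], ([], [], []))
        rec[0].append(snp)
        rec[1].append(_parse_int(row[3], path, lineno, "count_BY"))
        rec[2].append(_parse_int(row[4], path, lineno, "count_3S"))
    return {
        ind: SiteObservations(np.array(i), np.array(b), np.array(s), gmap.n_snps)
        for ind, (i, b, s) in per_ind.items()
    }


def write_genotype_matrix(matrix: np.ndarray, snp_index: np.ndarray, individuals, gmap: GenomeMap, path):
    """(SNPs x individuals) matrix of BY/3S/missing codes as B/S/N characters."""
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\t" + "\t".join(individuals) + "\n")
        for row, snp in zip(matrix, snp_index):
            chars = "\t".join(_STATE_CHARS[int(v)] for v in row)
            fh.write(f"{gmap.chrom_names[gmap.snp_chrom[snp]]}\t{to_disk_pos(gmap.snp_pos[snp])}\t{chars}\n")


def read_genotype_matrix(path, gmap: GenomeMap):
    """Returns (matrix, snp_index, individuals)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["chromosome", "position"]:
            raise ValueError(f"{path}: bad header {header[:2]}")
        individuals = header[2:]
        rows, snp_index = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            pos0 = from_disk_pos(_parse_int(row[1], path, lineno, "position"))
            try:
                snp_index.append(gmap.snp_index(row[0], pos0))
            except (KeyError, ValueError):
                raise ValueError(f"{path}:{lineno}: unknown SNP {row[0]}:{row[1]}") from None
            try:
                rows.append([_STATE_CODES[v] for v in row[2:]])
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: bad genotype character {exc.args[0]!r}") from None
    return np.array(rows, dtype=np.int8), np.array(snp_index, dtype=np.int64), individuals


# ---------------------------------------------------------------------------
# Phenotypes and class calls


def write_phenotypes(records, path):
    """``records``: iterable of PhenotypeRecord."""
    with open(path, "w") as fh:
        fh.write("individual\ttemperature\treplicate\tscore\n")
        for rec in records:
            for t in sorted(rec.scores):
                for ri, s in enumerate(rec.scores[t], start=1):
                    fh.write(f"{rec.individual}\t{t}\t{ri}\t{s}\n")


def read_phenotypes(path):
    from .phenotypes import PhenotypeRecord

    per_ind = {}
    for lineno, row in _read_rows(path, ("individual", "temperature", "replicate", "score")):
        t = _parse_int(row[1], path, lineno, "temperature")
        s = _parse_int(row[3], path, lineno, "score")
        if not 0 <= s <= 5:
            raise ValueError(f"{path}:{lineno}: score {s} outside [0, 5]")
        per_ind.setdefault(row[0], {}).setdefault(t, []).append(s)
    return [PhenotypeRecord(ind, scores) for ind, scores in per_ind.items()]


def write_class_calls(calls, path):
    with open(path, "w") as fh:
        fh.write("individual\tstate21\tstate30\tstate37\tclass\n")
        for c in calls:
            fh.write(f"{c.individual}\t{c.states[21]}\t{c.states[30]}\t{c.states[37]}\t{c.label}\n")


def read_class_calls(path) -> pd.DataFrame:
    rows = []
    for lineno, row in _read_rows(path, ("individual", "state21", "state30", "state37", "class")):
        rows.append(dict(zip(("individual", "state21", "state30", "state37", "class"), row)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scan artifacts


def write_regions(regions, gmap: GenomeMap, path):
    with open(path, "w") as fh:
        fh.write("region\tchromosome\tstart\tend\tn_snps\n")
        for i, reg in enumerate(regions):
            s1, e1 = to_disk_interval(reg.start, reg.end)
            fh.write(f"{i}\t{gmap.chrom_names[reg.chromosome]}\t{s1}\t{e1}\t{reg.n_snps}\n")


def write_pair_tests(tests: pd.DataFrame, path):
    tests.to_csv(path, sep="\t", index=False)


def write_loci(calls, path):
    from .bsa import loci_frame

    loci_frame(calls).to_csv(path, sep="\t", index=False)


def write_partition_calls(partition: dict, gmap: GenomeMap, path):
    with open(path, "w") as fh:
        fh.write("group_allele\tchromosome\tstart\tend\tallele\tn_snps\n")
        for group, payload in sorted(partition.items()):
            for _, row in payload["calls"].iterrows():
                s1, e1 = to_disk_interval(row["start"], row["end"])
                fh.write(
                    f"{group}\t{gmap.chrom_names[int(row['chromosome'])]}\t{s1}\t{e1}\t{row['allele']}\t{row['n_snps']}\n"
                )


# ---------------------------------------------------------------------------
# JSON artifacts


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Optional VCF import


def read_vcf_genotypes(path, gmap: GenomeMap | None = None):
    """Import a haploid VCF with GT fields as a genotype matrix.

    REF is taken as the BY allele and ALT as 3S; missing GT maps to N.
    Returns ``(matrix, snp_index_or_positions, individuals)``: when a genome
    map is supplied, rows are mapped onto its SNP indices (unknown sites
    raise); otherwise the second element is a list of ``(chrom, pos0)``.
    Requires pysam.
    """
    import pysam  # optional dependency, imported lazily

    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    rows, where = [], []
    for rec in vf:
        calls = []
        for sample in individuals:
            gt = rec.samples[sample].get("GT", (None,))
            a = gt[0] if gt else None
            calls.append(MISSING if a is None else (BY if a == 0 else S3))
        rows.append(calls)
        pos0 = rec.pos - 1  # pysam rec.pos is 1-based
        if gmap is not None:
            where.append(gmap.snp_index(rec.chrom, pos0))
        else:
            where.append((rec.chrom, pos0))
    matrix = np.array(rows, dtype=np.int8)
    if gmap is not None:
        where = np.array(where, dtype=np.int64)
    return matrix, where, individuals
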