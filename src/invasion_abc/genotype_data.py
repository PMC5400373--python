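"""Multi-population diploid microsatellite datasets and GenePop I/O.

Allele values are stored as integer repeat counts (not base-pair lengths), so
the stepwise mutation machinery can operate on them directly. Missing alleles
are coded by the reserved sentinel ``MISSING = 0``; every statistic downstream
must skip sentinel entries.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np

#: Reserved missing-allele sentinel (GenePop "000" / "000000").
MISSING: int = 0


class GenePopParseError(ValueError):
    """Malformed GenePop input; message names the offending line."""


class GenePopEncodeError(ValueError):
    """Dataset cannot be represented in the 3-digit GenePop dialect."""


@dataclass
class GenotypeDataset:
    """Diploid genotypes for one or more population samples.

    Parameters
    ----------
    populations
        Ordered unique population labels.
    loci
        Ordered locus labels.
    genotypes
        Mapping population label -> int array of shape
        ``(n_individuals, n_loci, 2)`` holding allele repeat counts, with
        ``MISSING`` (0) marking missing alleles.
    motif_lengths
        Repeat-motif length per locus (>=1); defaults to 1 for every locus.
    individual_ids
        Optional mapping population -> list of individual labels.
    """

    populations: list[str]
    loci: list[str]
    genotypes: dict[str, np.ndarray]
    motif_lengths: list[int] | None = None
    individual_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("dataset needs at least one population")
        if not self.loci:
            raise ValueError("dataset needs at least one locus")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population labels must be unique")
        if self.motif_lengths is None:
            self.motif_lengths = [1] * len(self.loci)
        if len(self.motif_lengths) != len(self.loci):
            raise ValueError("motif_lengths must match loci")
        if any(m < 1 for m in self.motif_lengths):
            raise ValueError("motif lengths must be >= 1")
        for pop in self.populations:
            if pop not in self.genotypes:
                raise ValueError(f"missing genotype table for population {pop!r}")
            arr = np.asarray(self.genotypes[pop], dtype=np.int64)
            if arr.ndim != 3 or arr.shape[1] != len(self.loci) or arr.shape[2] != 2:
                raise ValueError(
                    f"population {pop!r}: genotype table must have shape "
                    f"(n, {len(self.loci)}, 2), got {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"population {pop!r}: negative allele sizes")
            self.genotypes[pop] = arr

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_sizes(self) -> dict[str, int]:
        """Number of diploid individuals per population."""
        return {p: int(self.genotypes[p].shape[0]) for p in self.populations}

    def pop_alleles(self, pop: str, locus_index: int) -> np.ndarray:
        """Non-missing allele copies of one population at one locus."""
        a = self.genotypes[pop][:, locus_index, :].ravel()
        return a[a != MISSING]

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.populations == other.populations
            and self.loci == other.loci
            and self.motif_lengths == other.motif_lengths
            and all(
                np.array_equal(self.genotypes[p], other.genotypes[p])
                for p in self.populations
            )
        )


@dataclass(frozen=True)
class LocusQCRecord:
    """Estimated null-allele frequency of one locus in one population."""

    locus: str
    population: str
    null_freq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.null_freq <= 1.0:
            raise ValueError("null-allele frequency must lie in [0, 1]")


# ---------------------------------------------------------------------------
# GenePop dialect
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path: str) -> GenotypeDataset:
    """Parse a GenePop file (2- or 3-digit allele codes) into a dataset.

    The dialect accepted: a title line, locus names one per line or
    comma-separated on one line, ``POP`` separators, then individual lines
    ``id , a1a2 a1a2 ...``. Code 00/000 means missing.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenePopParseError("file too short to be GenePop")

    loci: list[str] = []
    i = 1  # skip title
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise GenePopParseError("no locus names before first POP")
    if i >= len(lines):
        raise GenePopParseError("no POP separator found")

    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            pops.append([])
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenePopParseError(f"line {lineno + 1}: missing ',' separator")
        ind_id, _, geno_part = line.partition(",")
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise GenePopParseError(
                f"line {lineno + 1}: expected {len(loci)} genotypes, got {len(codes)}"
            )
        genos: list[tuple[int, int]] = []
        for c in codes:
            if not c.isdigit() or len(c) not in (4, 6):
                raise GenePopParseError(
                    f"line {lineno + 1}: bad genotype code {c!r} "
                    "(need 4 or 6 digits)"
                )
            half = len(c) // 2
            genos.append((int(c[:half]), int(c[half:])))
        pops[-1].append((ind_id.strip(), genos))

    if not pops or any(len(p) == 0 for p in pops):
        raise GenePopParseError("empty population block")

    # GenePop convention: a population is named after its last individual's
    # identifier; our writer emits "<pop>_<index>" ids, so strip the trailing
    # index. Fall back to pop1..popN when that yields duplicates.
    candidates = [re.sub(r"_\d+$", "", block[-1][0]) for block in pops]
    if len(set(candidates)) == len(candidates) and all(candidates):
        populations = candidates
    else:
        populations = [f"pop{k + 1}" for k in range(len(pops))]
    genotypes: dict[str, np.ndarray] = {}
    individual_ids: dict[str, list[str]] = {}
    for label, block in zip(populations, pops):
        arr = np.array([g for _, g in block], dtype=np.int64)
        genotypes[label] = arr
        individual_ids[label] = [iid for iid, _ in block]
    return GenotypeDataset(
        populations=populations,
        loci=loci,
        genotypes=genotypes,
        individual_ids=individual_ids,
    )


def write_genepop(dataset: GenotypeDataset, path: str, title: str = "invasion-abc export") -> None:
    """Write a dataset in the 3-digit GenePop dialect (missing = ``000000``)."""
    for pop in dataset.populations:
        if np.any(dataset.genotypes[pop] > 999):
            raise GenePopEncodeError(
                f"population {pop!r} has allele sizes > 999; "
                "cannot encode in 3-digit GenePop"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for locus in dataset.loci:
            fh.write(locus + "\n")
        for pop in dataset.populations:
            fh.write("POP\n")
            arr = dataset.genotypes[pop]
            ids = dataset.individual_ids.get(
                pop, [f"{pop}_{k + 1}" for k in range(arr.shape[0])]
            )
            for iid, row in zip(ids, arr):
                codes = " ".join(f"{a:03d}{b:03d}" for a, b in row)
                fh.write(f"{iid} , {codes}\n")


def subset_populations(dataset: GenotypeDataset, pops: list[str]) -> GenotypeDataset:
    """Dataset restricted to ``pops``, in the given order."""
    missing = [p for p in pops if p not in dataset.populations]
    if missing:
        raise KeyError(f"unknown populations: {missing}")
    return GenotypeDataset(
        populations=list(pops),
        loci=list(dataset.loci),
        genotypes={p: dataset.genotypes[p].copy() for p in pops},
        motif_lengths=list(dataset.motif_lengths),
        individual_ids={
            p: list(dataset.individual_ids[p])
            for p in pops
            if p in dataset.individual_ids
        },
    )


# ---------------------------------------------------------------------------
# Locus QC filter
# ---------------------------------------------------------------------------

def read_locus_qc(path: str) -> list[LocusQCRecord]:
    """Read QC records from a CSV with columns locus,population,null_freq."""
    records: list[LocusQCRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                LocusQCRecord(row["locus"], row["population"], float(row["null_freq"]))
            )
    return records


def filter_loci_by_null_alleles(
    dataset: GenotypeDataset,
    qc: list[LocusQCRecord],
    threshold: float = 0.10,
) -> GenotypeDataset:
    """Drop every locus whose null-allele frequency exceeds ``threshold`` in
    any population (strict ``>``); remaining locus order is preserved.

    Each dataset locus must carry at least one QC record; frequencies are
    supplied externally rather than estimated here.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    by_locus: dict[str, list[float]] = {}
    for rec in qc:
        by_locus.setdefault(rec.locus, []).append(rec.null_freq)
    missing = [loc for loc in dataset.loci if loc not in by_locus]
    if missing:
        raise KeyError(f"no QC record for loci: {missing}")
    keep = [j for j, loc in enumerate(dataset.loci) if max(by_locus[loc]) <= threshold]
    if not keep:
        raise ValueError("all loci excluded by the null-allele filter")
    return GenotypeDataset(
        populations=list(dataset.populations),
        loci=[dataset.loci[j] for j in keep],
        genotypes={
            p: dataset.genotypes[p][:, keep, :] for p in dataset.populations
        },
        motif_lengths=[dataset.motif_lengths[j] for j in keep],
        individual_ids=dict(dataset.individual_ids),
    )
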