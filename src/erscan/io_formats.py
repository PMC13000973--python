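"""Exchange formats for pool-seq E&R data.

The canonical input is the PoPoolation2 "sync" dialect: one line per genomic
site, tab-separated ``chrom  pos  ref`` followed by one colon-separated count
6-tuple per pool in the fixed allele order A:T:C:G:N:del.  Gene models come in
as GFF3 (optionally with a two-column gene→GO side table), candidate intervals
go out as BED.  Coordinates are 1-based inclusive everywhere internally; only
BED output is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: allele order of the sync count tuples
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: indices of the four real nucleotides within a count 6-tuple
_NUC_IDX = {a: i for i, a in enumerate(SYNC_ALLELES[:4])}

TEMPERATURES = ("ambient", "hot")
POLLINATIONS = ("bumblebee", "butterfly", "generalised", "control")


class SyncParseError(ValueError):
    """Malformed sync line (wrong column count or non-integer count)."""


class ConfigError(ValueError):
    """Inconsistent configuration (design mismatch, bad thresholds...)."""


@dataclass(frozen=True)
class SyncRecord:
    """One genomic site with per-pool read counts in A,T,C,G,N,del order."""

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # shape (n_pools, 6), non-negative ints

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim == 1:
            counts = counts[None, :]
        if counts.shape[-1] != 6 or (counts < 0).any():
            raise ValueError("counts must be non-negative 6-vectors per pool")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class PoolDesign:
    """One sequenced pool: regime labels, pool size and Ne trajectory.

    ``ne_trajectory`` holds the per-generation realised effective sizes
    N_e,g of the replicate line (length = number of generations); it is empty
    for the ancestral G1 pool, which did not evolve.
    """

    pool_id: str
    temperature: str
    pollination: str
    replicate: str
    n_individuals: int
    ne_trajectory: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.temperature not in TEMPERATURES + ("ancestral",):
            raise ValueError(f"unknown temperature {self.temperature!r}")
        if self.pollination not in POLLINATIONS + ("ancestral",):
            raise ValueError(f"unknown pollination {self.pollination!r}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if any(ne < 1 for ne in self.ne_trajectory):
            raise ValueError("every N_e,g must be >= 1")
        object.__setattr__(self, "ne_trajectory", tuple(int(x) for x in self.ne_trajectory))

    @property
    def is_ancestral(self) -> bool:
        return len(self.ne_trajectory) == 0

    @property
    def treatment(self) -> str:
        return f"{self.temperature}-{self.pollination}"


@dataclass(frozen=True)
class GeneModel:
    """A gene feature with 1-based inclusive coordinates and GO annotations."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    description: str = ""
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        object.__setattr__(self, "go_terms", frozenset(self.go_terms))


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def read_sync(path, design: Sequence[PoolDesign] | None = None,
              n_pools: int | None = None) -> list[SyncRecord]:
    """Parse a sync file into :class:`SyncRecord` objects.

    Pool columns are taken in file order, which must match the order of
    ``design`` when one is given.  Raises :class:`SyncParseError` naming the
    offending line on malformed input and :class:`ConfigError` when the pool
    count disagrees with the design.
    """
    if design is not None:
        n_pools = len(design)
    records: list[SyncRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(f"{path}: line {lineno}: expected >= 4 columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(f"{path}: line {lineno}: bad position {pos_s!r}") from None
            pools = fields[3:]
            if n_pools is not None and len(pools) != n_pools:
                raise ConfigError(
                    f"{path}: line {lineno}: {len(pools)} pool columns, design has {n_pools}")
            counts = np.empty((len(pools), 6), dtype=np.int64)
            for j, tup in enumerate(pools):
                parts = tup.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"{path}: line {lineno}: count field {tup!r} is not a 6-tuple")
                try:
                    counts[j] = [int(x) for x in parts]
                except ValueError:
                    raise SyncParseError(
                        f"{path}: line {lineno}: non-integer count in {tup!r}") from None
            records.append(SyncRecord(chrom, pos, ref, counts))
    return records


def write_sync(records: Iterable[SyncRecord], path) -> None:
    """Write records in the sync dialect (inverse of :func:`read_sync`)."""
    with open(path, "w") as fh:
        for rec in records:
            pools = "\t".join(":".join(str(c) for c in row) for row in rec.counts)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{pools}\n")


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def sites_to_frequencies(records: Sequence[SyncRecord],
                         design: Sequence[PoolDesign],
                         ancestral: str | None = None,
                         min_count: int = 12,
                         min_cov: int = 18,
                         max_cov: int = 150) -> pd.DataFrame:
    """Filter sites and derive per-pool minor-allele frequencies.

    A site is retained when (i) after summing counts over all pools exactly
    two nucleotide alleles are present, neither N nor a deletion, (ii) the
    summed minor-allele count reaches ``min_count`` (PoPoolation2 semantics:
    the threshold applies to the sum over pools, not per pool), and (iii)
    every pool's total depth lies within ``[min_cov, max_cov]``.

    The minor allele is the less frequent allele in the ancestral pool
    (``ancestral`` pool_id, default: the design's ancestral entry, else the
    first pool), held fixed across all pools so that downstream ΔAF signs are
    comparable; ties at 0.5 break alphabetically.

    Returns a DataFrame with columns ``chrom, pos, major, minor`` and per pool
    ``depth_<id>`` and ``freq_<id>`` (minor-allele read frequency).
    """
    if min_count < 1 or min_cov < 1 or max_cov < 1:
        raise ConfigError("thresholds must be positive")
    if min_cov > max_cov:
        raise ConfigError(f"min_cov {min_cov} > max_cov {max_cov}")
    pool_ids = [d.pool_id for d in design]
    if ancestral is None:
        anc = [d.pool_id for d in design if d.is_ancestral]
        ancestral = anc[0] if anc else pool_ids[0]
    if ancestral not in pool_ids:
        raise ConfigError(f"ancestral pool {ancestral!r} not in design")
    anc_idx = pool_ids.index(ancestral)

    rows = []
    for rec in records:
        if rec.n_pools != len(design):
            raise ConfigError(
                f"record {rec.chrom}:{rec.pos} has {rec.n_pools} pools, design {len(design)}")
        depth = rec.counts.sum(axis=1)
        if (depth < min_cov).any() or (depth > max_cov).any():
            continue
        total = rec.counts.sum(axis=0)  # summed over pools, length 6
        present = np.nonzero(total)[0]
        if len(present) != 2:
            continue
        if any(i >= 4 for i in present):  # N or del among the two alleles
            continue
        a1, a2 = (SYNC_ALLELES[i] for i in present)
        if total[present[0]] <= total[present[1]]:
            lo_i, hi_i = present[0], present[1]
        else:
            lo_i, hi_i = present[1], present[0]
        if total[lo_i] < min_count:
            continue
        # polarise on the ancestral pool
        anc_depth = depth[anc_idx]
        f1 = rec.counts[anc_idx, present[0]] / anc_depth
        f2 = rec.counts[anc_idx, present[1]] / anc_depth
        if f1 < f2:
            minor_i, major_i = present[0], present[1]
        elif f2 < f1:
            minor_i, major_i = present[1], present[0]
        else:  # tie: alphabetical allele order
            minor_i, major_i = sorted(present, key=lambda i: SYNC_ALLELES[i])
        row = {"chrom": rec.chrom, "pos": rec.pos,
               "major": SYNC_ALLELES[major_i], "minor": SYNC_ALLELES[minor_i]}
        for j, pid in enumerate(pool_ids):
            row[f"depth_{pid}"] = int(depth[j])
            row[f"freq_{pid}"] = rec.counts[j, minor_i] / depth[j]
        rows.append(row)

    cols = ["chrom", "pos", "major", "minor"]
    for pid in pool_ids:
        cols += [f"depth_{pid}", f"freq_{pid}"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# design table
# ---------------------------------------------------------------------------

def read_design(path) -> list[PoolDesign]:
    """Read the experiment-design TSV (pool_id, temperature, pollination,
    replicate, n_individuals, ne_trajectory as comma-separated integers)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        traj = tuple()
        raw = r.get("ne_trajectory")
        if isinstance(raw, str) and raw.strip():
            traj = tuple(int(x) for x in raw.split(","))
        out.append(PoolDesign(r["pool_id"], r["temperature"], r["pollination"],
                              r["replicate"], int(r["n_individuals"]), traj))
    return out


def write_design(design: Sequence[PoolDesign], path) -> None:
    rows = [{"pool_id": d.pool_id, "temperature": d.temperature,
             "pollination": d.pollination, "replicate": d.replicate,
             "n_individuals": d.n_individuals,
             "ne_trajectory": ",".join(str(x) for x in d.ne_trajectory)}
            for d in design]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 / GO side table / BED
# ---------------------------------------------------------------------------

def read_go_table(path) -> dict[str, set[str]]:
    """Two-column TSV gene_id → GO id (one pair per line)."""
    mapping: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"],
                     dtype=str, comment="#")
    for gid, go in zip(df["gene_id"], df["go_id"]):
        mapping.setdefault(gid, set()).add(go)
    return mapping


def read_gff(path, go_table: dict[str, set[str]] | str | Path | None = None,
             feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models from GFF3, with GO terms inline (Ontology_term) or
    from a side table.  Features lacking an ID attribute are skipped with a
    warning."""
    import gffutils

    if go_table is not None and not isinstance(go_table, dict):
        go_table = read_go_table(go_table)
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [None])[0]
        if gid is None:
            warnings.warn(f"{path}: {feature_type} feature at "
                          f"{feat.seqid}:{feat.start} lacks ID; skipped")
            continue
        go_terms: set[str] = set(feat.attributes.get("Ontology_term", []))
        if go_table:
            go_terms |= go_table.get(gid, set())
        desc = feat.attributes.get("description", [""])[0]
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end,
                               feat.strand or ".", desc, frozenset(go_terms)))
    return genes


def write_bed(intervals, path) -> None:
    """Write candidate intervals as BED (0-based half-open), sorted by
    (chrom, start).  ``intervals`` is an iterable of objects or mappings with
    chrom / start / end and an optional name or label."""
    rows = []
    for iv in intervals:
        get = iv.get if isinstance(iv, dict) else lambda k, d=None: getattr(iv, k, d)
        name = get("name", None) or get("label", None) or \
            f"{get('chrom')}:{get('start')}-{get('end')}"
        rows.append((get("chrom"), int(get("start")) - 1, int(get("end")), name))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for chrom, s, e, name in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
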