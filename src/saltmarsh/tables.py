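"""Readers, writers and containers for count tables, metadata and sensor series.

Formats are deliberately plain: tab-separated count tables (first column =
taxon id, header row = sample ids), QIIME-style mapping files, semicolon
lineage strings, newick trees and CSV sensor records. The dense-JSON BIOM
dialect is supported for interchange with QIIME-era tooling.

Parsers validate rather than coerce: duplicate identifiers, negative or
non-integer counts, out-of-vocabulary metadata and non-uniform sensor
timestamps are all hard errors naming the offender.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

TREATMENTS = ("enriched", "reference")
HABITATS = ("TSA", "SP")

#: taxonomic ranks of a 7-level lineage, kingdom to species
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

UNCLASSIFIED = "unclassified"


class ParseError(ValueError):
    """A file violated the format contract; the message names the offender."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ParseError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """A taxa-by-samples matrix of sequence read counts.

    ``counts[i, j]`` is the number of reads of taxon ``taxon_ids[i]`` in
    sample ``sample_ids[j]``. Counts are non-negative integers; all-zero
    rows are permitted (a taxon absent from every retained sample).
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (taxa x samples)")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        _check_unique(self.taxon_ids, "taxon id")
        _check_unique(self.sample_ids, "sample id")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample (library sizes)."""
        return self.counts.sum(axis=0)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class PairedCommunityTable:
    """Aligned DNA (rRNA gene) and RNA (rRNA) count matrices.

    Both matrices share one taxon ordering and one sample ordering; each
    sample id names a biological sample from which both molecules were
    sequenced. ``metadata``, when present, is indexed by those sample ids.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    dna: np.ndarray
    rna: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dna = np.asarray(self.dna)
        self.rna = np.asarray(self.rna)
        shape = (len(self.taxon_ids), len(self.sample_ids))
        for name, m in (("dna", self.dna), ("rna", self.rna)):
            if m.shape != shape:
                raise ValueError(f"{name} matrix shape {m.shape} != {shape}")
            if not np.issubdtype(m.dtype, np.integer) or np.any(m < 0):
                raise ValueError(f"{name} matrix must hold non-negative integers")
        _check_unique(self.taxon_ids, "taxon id")
        _check_unique(self.sample_ids, "sample id")
        if self.metadata is not None:
            missing = set(self.sample_ids) - set(self.metadata.index)
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def dna_table(self) -> CountTable:
        return CountTable(list(self.taxon_ids), list(self.sample_ids), self.dna)

    def rna_table(self) -> CountTable:
        return CountTable(list(self.taxon_ids), list(self.sample_ids), self.rna)


@dataclass
class TaxonomyMap:
    """Taxon id -> ordered lineage (kingdom ... species, <=7 ranks).

    Missing taxa and unresolved ranks resolve to ``"unclassified"`` so that
    rank lookups are total over any taxon set.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, lineage in self.lineages.items():
            if len(lineage) > len(RANKS):
                raise ValueError(f"lineage of {taxon!r} has more than 7 ranks")

    def rank(self, taxon_id: str, rank: str) -> str:
        """Return the named rank of a taxon, ``"unclassified"`` if unresolved."""
        i = RANKS.index(rank)
        lineage = self.lineages.get(taxon_id, ())
        if i >= len(lineage):
            return UNCLASSIFIED
        value = lineage[i].strip()
        return value if value else UNCLASSIFIED

    def order(self, taxon_id: str) -> str:
        return self.rank(taxon_id, "order")

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class TidalCreekSeries:
    """Uniformly sampled sonde + pressure-logger record for one tidal creek.

    Columns: depth (m), temperature (deg C), salinity (practical), wind and
    current speed (m s^-1), and exactly one of o2_saturation (%) or
    o2_concentration (mmol m^-3). Timestamps must be strictly increasing
    with a constant step.
    """

    data: pd.DataFrame

    REQUIRED = ("depth", "temperature", "salinity", "wind", "current")

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("series must be indexed by timestamps")
        steps = np.diff(df.index.view("int64"))
        if len(steps) == 0:
            raise ValueError("series needs at least two samples")
        if np.any(steps <= 0) or len(set(steps)) != 1:
            raise ValueError("timestamps must be strictly increasing with constant step")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"missing column: {col}")
        has_sat = "o2_saturation" in df.columns
        has_conc = "o2_concentration" in df.columns
        if has_sat == has_conc:
            raise ValueError("exactly one of o2_saturation / o2_concentration required")
        if (df["depth"] < 0).any():
            raise ValueError("depth must be >= 0")
        if (df["salinity"] < 0).any():
            raise ValueError("salinity must be >= 0")

    @property
    def dt_minutes(self) -> float:
        return float((self.data.index[1] - self.data.index[0]).total_seconds() / 60.0)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path: str | Path, dialect: Literal["tsv", "biom_json"] = "tsv") -> CountTable:
    """Read a taxa-by-samples count table from TSV or dense-JSON BIOM."""
    path = Path(path)
    if dialect == "tsv":
        return _read_count_tsv(path)
    if dialect == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_count_tsv(path: Path) -> CountTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: malformed header (need >=1 sample column): {lines[0]!r}")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample id")
    taxon_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
        taxon_ids.append(cells[0])
        row = []
        for cell in cells[1:]:
            try:
                v = int(cell)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer count {cell!r}") from None
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative count {v}")
            row.append(v)
        rows.append(row)
    _check_unique(taxon_ids, "taxon id")
    counts = np.asarray(rows, dtype=np.int64).reshape(len(taxon_ids), len(sample_ids))
    return CountTable(taxon_ids, sample_ids, counts)


def write_count_table(table: CountTable, path: str | Path,
                      dialect: Literal["tsv", "biom_json"] = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
            for taxon, row in zip(table.taxon_ids, table.counts):
                fh.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    elif dialect == "biom_json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "saltmarsh",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": list(table.shape),
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def _read_biom_json(path: Path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ParseError(f"{path}: only dense BIOM JSON is supported")
    taxon_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = np.asarray(doc["data"])
    try:
        return CountTable(taxon_ids, sample_ids, counts)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# pairing


def strip_molecule_suffix(sample_id: str,
                          suffixes: Sequence[str] = ("_DNA", "_cDNA", "_RNA")) -> str:
    for suf in suffixes:
        if sample_id.endswith(suf):
            return sample_id[: -len(suf)]
    return sample_id


def align_paired(dna: CountTable, rna: CountTable,
                 metadata: pd.DataFrame | None = None,
                 taxon_policy: Literal["union", "intersection"] = "union",
                 suffixes: Sequence[str] = ("_DNA", "_cDNA", "_RNA"),
                 ) -> PairedCommunityTable:
    """Align a DNA and an RNA count table into one paired structure.

    Library ids carry a molecule suffix (``S1_DNA`` / ``S1_cDNA`` by
    convention); the suffix is stripped and libraries sharing a base id are
    paired. Taxa are harmonized per ``taxon_policy``: ``union`` keeps every
    taxon seen in either table (missing rows zero-padded, as required by the
    convention that an RNA-only taxon is presumed present but unsequenced in
    the DNA library), ``intersection`` keeps shared taxa only.
    """
    dna_base = [strip_molecule_suffix(s, suffixes) for s in dna.sample_ids]
    rna_base = [strip_molecule_suffix(s, suffixes) for s in rna.sample_ids]
    _check_unique(dna_base, "DNA sample id (after suffix strip)")
    _check_unique(rna_base, "RNA sample id (after suffix strip)")
    only_dna = sorted(set(dna_base) - set(rna_base))
    only_rna = sorted(set(rna_base) - set(dna_base))
    if only_dna or only_rna:
        raise ValueError(
            f"unmatched samples: DNA-only={only_dna}, RNA-only={only_rna}"
        )
    sample_ids = list(dna_base)  # preserve DNA table order

    if taxon_policy == "union":
        taxa = list(dna.taxon_ids) + [t for t in rna.taxon_ids if t not in set(dna.taxon_ids)]
    elif taxon_policy == "intersection":
        rna_set = set(rna.taxon_ids)
        taxa = [t for t in dna.taxon_ids if t in rna_set]
    else:
        raise ValueError(f"unknown taxon_policy: {taxon_policy!r}")

    def reindex(table: CountTable, base_ids: list[str]) -> np.ndarray:
        out = np.zeros((len(taxa), len(sample_ids)), dtype=np.int64)
        row_of = {t: i for i, t in enumerate(table.taxon_ids)}
        col_of = {b: j for j, b in enumerate(base_ids)}
        cols = [col_of[s] for s in sample_ids]
        for i, t in enumerate(taxa):
            if t in row_of:
                out[i] = table.counts[row_of[t]][cols]
        return out

    meta = None
    if metadata is not None:
        missing = set(sample_ids) - set(metadata.index)
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)}")
        meta = metadata.loc[sample_ids]
    return PairedCommunityTable(taxa, sample_ids, reindex(dna, dna_base),
                                reindex(rna, rna_base), meta)


# ---------------------------------------------------------------------------
# metadata / taxonomy / tree / sensor series


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a QIIME-style mapping TSV (header starts ``#SampleID``).

    Returns a DataFrame indexed by sample id with at least ``treatment``
    (enriched/reference) and ``habitat`` (TSA/SP) columns; ``date`` is
    parsed to a datetime and ``replicate`` to an integer when present.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#SampleID"):
        raise ParseError(f"{path}: mapping file must start with '#SampleID' header")
    header = lines[0].lstrip("#").split("\t")
    records = [ln.split("\t") for ln in lines[1:] if not ln.startswith("#")]
    df = pd.DataFrame(records, columns=header).set_index("SampleID")
    df.index.name = "sample_id"
    _check_unique(list(df.index), "sample id")
    if "treatment" in df.columns:
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise ParseError(f"{path}: treatment not in {TREATMENTS}: {sorted(bad)}")
    if "habitat" in df.columns:
        bad = set(df["habitat"]) - set(HABITATS)
        if bad:
            raise ParseError(f"{path}: habitat not in {HABITATS}: {sorted(bad)}")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    df = metadata.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        fh.write("#SampleID\t" + "\t".join(df.columns) + "\n")
        for sid, row in df.iterrows():
            fh.write(str(sid) + "\t" + "\t".join(str(v) for v in row) + "\n")


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage, trimming Greengenes-style
    rank prefixes (``k__``, ``p__``...) and whitespace."""
    parts = []
    for raw in lineage.split(";"):
        part = raw.strip()
        if len(part) >= 3 and part[1:3] == "__":
            part = part[3:]
        parts.append(part if part else UNCLASSIFIED)
    return tuple(parts)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of taxon id -> semicolon-delimited lineage."""
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            cells = ln.rstrip("\n").split("\t")
            if len(cells) < 2:
                raise ParseError(f"{path}:{lineno}: expected taxon<TAB>lineage")
            taxon = cells[0]
            if taxon in lineages:
                raise ParseError(f"{path}:{lineno}: duplicate taxon id {taxon!r}")
            lineage = parse_lineage(cells[1])
            if len(lineage) > len(RANKS):
                raise ParseError(f"{path}:{lineno}: lineage has more than 7 ranks")
            lineages[taxon] = lineage
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, lineage in taxonomy.lineages.items():
            fh.write(taxon + "\t" + ";".join(lineage) + "\n")


def read_tree(source: str | Path) -> TreeNode:
    """Read a rooted newick tree, enforcing non-negative branch lengths and
    unique leaf names. Accepts a path or a newick string."""
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    tree = TreeNode.read(io.StringIO(text))
    names = [leaf.name for leaf in tree.tips()]
    _check_unique(names, "leaf name")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ParseError(f"negative branch length at node {node.name!r}")
    return tree


def read_creek_series(path: str | Path) -> TidalCreekSeries:
    """Read a CSV sensor series with an ISO ``timestamp`` column."""
    df = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    return TidalCreekSeries(df)


def write_creek_series(series: TidalCreekSeries, path: str | Path) -> None:
    series.data.to_csv(path, index_label="timestamp")
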