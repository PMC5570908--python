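"""Domain types and file I/O for E3-substrate interaction prediction.

All identifiers are opaque, case-sensitive accession strings; no accession
mapping is performed.  An E3-substrate interaction (ESI) is a *directed*
pair (e3, substrate); the protein-protein interaction network is the only
undirected structure in the package.

Supported dialects:

* pair lists      -- TSV: e3, substrate[, pubmed[, date]]
* annotations     -- two-column TSV (protein, label) or GAF 2.x for GO
* PPI network     -- edge-list TSV / PSI-MI TAB (first two columns)
* ortholog map    -- two-column TSV (source_id, target_id)
* sequences       -- FASTA, accession = first whitespace token of header
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: residues accepted in sequence input (20 canonical + X for unknown)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class ParseError(ValueError):
    """Malformed input line; message names the offending line number."""


class EmptyInputError(ValueError):
    """A loader produced zero records."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def validate_protein_id(pid: str) -> str:
    if not pid or any(c.isspace() for c in pid):
        raise ValueError(f"invalid protein id: {pid!r}")
    return pid


@dataclass(frozen=True, slots=True, order=True)
class ESIPair:
    """Directed E3 -> substrate pair.  (a, b) != (b, a)."""

    e3: str
    substrate: str
    self_interaction: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        validate_protein_id(self.e3)
        validate_protein_id(self.substrate)
        if self.e3 == self.substrate and not self.self_interaction:
            raise ValueError(
                f"self pair {self.e3!r}: pass self_interaction=True to assert "
                "autoubiquitination"
            )


@dataclass(frozen=True)
class GoldStandard:
    """Labeled positive (GSP) and negative (GSN) ESI sets."""

    positives: frozenset[ESIPair]
    negatives: frozenset[ESIPair]
    provenance: Mapping[ESIPair, tuple[str | None, _dt.date | None]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:3]}")

    @property
    def t(self) -> int:
        return len(self.positives)

    @property
    def f(self) -> int:
        return len(self.negatives)

    def require_nonempty(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both positive and negative sets must be non-empty")


@dataclass(frozen=True)
class AnnotationMap:
    """protein -> set of labels, in a single namespace ('domain' or 'go')."""

    namespace: str
    _labels: Mapping[str, frozenset[str]]

    def labels(self, protein: str) -> frozenset[str]:
        return self._labels.get(protein, frozenset())

    def proteins(self) -> frozenset[str]:
        return frozenset(self._labels)

    def items(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self._labels.items())

    def __len__(self) -> int:
        return len(self._labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self.namespace == other.namespace and dict(self._labels) == dict(
            other._labels
        )


class PPINetwork:
    """Undirected simple graph over protein ids (no self-loops, no multi-edges)."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        g = nx.Graph()
        dropped = 0
        for a, b in edges:
            validate_protein_id(a)
            validate_protein_id(b)
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
        if dropped:
            logger.info("dropped %d self-loop(s) while building PPI network", dropped)
        self._g = g
        self.n_self_loops_dropped = dropped

    @property
    def graph(self) -> nx.Graph:
        return self._g

    def neighbors(self, protein: str) -> frozenset[str]:
        if protein not in self._g:
            return frozenset()
        return frozenset(self._g.neighbors(protein))

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def degree(self, protein: str) -> int:
        return self._g.degree(protein) if protein in self._g else 0

    def edges(self) -> list[tuple[str, str]]:
        """Edges in canonical (min, max) order, sorted."""
        return sorted(tuple(sorted(e)) for e in self._g.edges())

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.edges() == other.edges()


@dataclass(frozen=True)
class OrthologMap:
    """source-species protein -> set of target-species proteins (one-to-many)."""

    _map: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def orthologs(self, source: str) -> frozenset[str]:
        return self._map.get(source, frozenset())

    def items(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self._map.items())

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologMap):
            return NotImplemented
        return dict(self._map) == dict(other._map)


class SequenceSet(dict):
    """protein id -> uppercase amino-acid sequence (20-letter alphabet + X)."""

    def __setitem__(self, key: str, seq: str) -> None:
        validate_protein_id(key)
        if not seq:
            raise ValueError(f"empty sequence for {key!r}")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"illegal residue(s) {sorted(bad)} in sequence {key!r}")
        super().__setitem__(key, seq)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_date(token: str, path: str | Path, lineno: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad date {token!r}") from exc


def load_gold_standard(
    path: str | Path,
    date_cutoff: _dt.date | None = None,
    *,
    keep: str = "before",
    allow_self: bool = False,
) -> tuple[frozenset[ESIPair], dict[ESIPair, tuple[str | None, _dt.date | None]]]:
    """Load one side (positives or negatives) of a gold standard pair list.

    Rows are ``e3<TAB>substrate[<TAB>pubmed[<TAB>date]]``.  With a
    ``date_cutoff``, rows are kept strictly before (``keep="before"``) or on/
    after (``keep="after"``) the cutoff; rows without a date are dropped when
    filtering.  Duplicate rows collapse to a single pair.
    """
    if keep not in ("before", "after"):
        raise ValueError(f"keep must be 'before' or 'after', got {keep!r}")
    pairs: set[ESIPair] = set()
    provenance: dict[ESIPair, tuple[str | None, _dt.date | None]] = {}
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        e3, sub = cols[0].strip(), cols[1].strip()
        if not e3 or not sub:
            raise ParseError(f"{path}:{lineno}: empty protein id")
        pubmed = cols[2].strip() or None if len(cols) > 2 else None
        date = None
        if len(cols) > 3 and cols[3].strip():
            date = _parse_date(cols[3].strip(), path, lineno)
        if date_cutoff is not None:
            if date is None:
                continue
            if keep == "before" and not (date < date_cutoff):
                continue
            if keep == "after" and not (date >= date_cutoff):
                continue
        if e3 == sub and not allow_self:
            raise ParseError(
                f"{path}:{lineno}: self pair {e3!r} (pass allow_self=True to accept)"
            )
        pair = ESIPair(e3, sub, self_interaction=(e3 == sub))
        pairs.add(pair)
        provenance.setdefault(pair, (pubmed, date))
    if not pairs:
        raise EmptyInputError(f"{path}: no pairs loaded")
    return frozenset(pairs), provenance


_GAF_NCOLS_MIN = 15


def _looks_like_gaf(path: str | Path) -> bool:
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("!"):
                return True
            if not raw.strip():
                continue
            return len(raw.rstrip("\n").split("\t")) >= _GAF_NCOLS_MIN
    return False


def load_annotations(path: str | Path, namespace: str) -> AnnotationMap:
    """Load protein -> label annotations.

    ``namespace`` is ``"domain"`` or ``"go"``.  Accepts a two-column TSV for
    either namespace; for GO additionally the GAF 2.x dialect (DB Object ID =
    column 2, qualifier = column 4, GO ID = column 5; ``NOT`` rows skipped).
    """
    if namespace not in ("domain", "go"):
        raise ValueError(f"unknown annotation namespace {namespace!r}")
    mapping: dict[str, set[str]] = {}
    if namespace == "go" and _looks_like_gaf(path):
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                if raw.startswith("!") or not raw.strip():
                    continue
                cols = raw.rstrip("\n").split("\t")
                if len(cols) < _GAF_NCOLS_MIN:
                    raise ParseError(f"{path}:{lineno}: short GAF line")
                if "NOT" in cols[3].split("|"):
                    continue
                mapping.setdefault(cols[1], set()).add(cols[4])
    else:
        for lineno, cols in _data_lines(path):
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            protein, label = cols[0].strip(), cols[1].strip()
            if not protein or not label:
                raise ParseError(f"{path}:{lineno}: empty field")
            mapping.setdefault(protein, set()).add(label)
    if not mapping:
        raise EmptyInputError(f"{path}: zero annotations parsed")
    return AnnotationMap(namespace, {p: frozenset(ls) for p, ls in mapping.items()})


def load_network(path: str | Path) -> PPINetwork:
    """Load an undirected PPI network from an edge-list TSV.

    Only the first two columns are used, so a PSI-MI TAB file works as-is.
    Self-loops are dropped (counted), duplicate edges merged.
    """
    edges = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 columns")
        a, b = cols[0].strip(), cols[1].strip()
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty protein id")
        edges.append((a, b))
    net = PPINetwork(edges)
    if net.number_of_edges() == 0:
        raise EmptyInputError(f"{path}: no edges loaded")
    return net


def load_ortholog_map(path: str | Path) -> OrthologMap:
    """Load a two-column (source_id, target_id) ortholog map; one-to-many."""
    mapping: dict[str, set[str]] = {}
    for lineno, cols in _data_lines(path):
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        src, tgt = cols[0].strip(), cols[1].strip()
        if not src or not tgt:
            raise ParseError(f"{path}:{lineno}: empty field")
        mapping.setdefault(src, set()).add(tgt)
    return OrthologMap({s: frozenset(t) for s, t in mapping.items()})


def load_sequences(path: str | Path) -> SequenceSet:
    """Load a FASTA file; the accession is the first token of each header."""
    seqs = SequenceSet()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {record.id!r}")
        seqs[record.id] = seq
    if not seqs:
        raise EmptyInputError(f"{path}: no FASTA records")
    return seqs


# ---------------------------------------------------------------------------
# writers (canonical TSV/FASTA; sorted for byte-stable output)
# ---------------------------------------------------------------------------


def write_pairs(
    pairs: Iterable[ESIPair],
    path: str | Path,
    provenance: Mapping[ESIPair, tuple[str | None, _dt.date | None]] | None = None,
) -> None:
    with open(path, "w") as fh:
        for pair in sorted(pairs):
            row = [pair.e3, pair.substrate]
            if provenance is not None:
                pubmed, date = provenance.get(pair, (None, None))
                row += [pubmed or "", date.isoformat() if date else ""]
            fh.write("\t".join(row).rstrip("\t") + "\n")


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein in sorted(ann.proteins()):
            for label in sorted(ann.labels(protein)):
                fh.write(f"{protein}\t{label}\n")


def write_gaf(ann: AnnotationMap, path: str | Path) -> None:
    """Write GO annotations as a minimal valid GAF 2.2 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein in sorted(ann.proteins()):
            for label in sorted(ann.labels(protein)):
                cols = ["DB", protein, protein, "enables", label, "PMID:0", "IEA",
                        "", "F", "", "", "protein", "taxon:9606", "20140101", "DB",
                        "", ""]
                fh.write("\t".join(cols) + "\n")


def write_network(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in net.edges():
            fh.write(f"{a}\t{b}\n")


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src in sorted(dict(omap.items())):
            for tgt in sorted(omap.orthologs(src)):
                fh.write(f"{src}\t{tgt}\n")


def write_sequences(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seqs[pid]), id=pid, description="") for pid in sorted(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# negative-set sampling
# ---------------------------------------------------------------------------


def sample_negative_set(
    ppi: PPINetwork,
    e3_list: Iterable[str],
    gsp: frozenset[ESIPair] | set[ESIPair],
    n: int,
    seed: int,
) -> frozenset[ESIPair]:
    """Sample ``n`` E3-interactor pairs from PPI edges incident to the E3 list.

    Pairs already in the positive set are excluded before sampling.  The draw
    is uniform without replacement and reproducible from ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    e3s = sorted(set(e3_list))
    positive_keys = {(p.e3, p.substrate) for p in gsp}
    eligible: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for e3 in e3s:
        for nb in sorted(ppi.neighbors(e3)):
            key = (e3, nb)
            if key in positive_keys or key in seen or e3 == nb:
                continue
            seen.add(key)
            eligible.append(key)
    if n > len(eligible):
        raise ValueError(
            f"requested {n} negative pairs but only {len(eligible)} eligible "
            "E3-interactor pairs are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return frozenset(ESIPair(*eligible[i]) for i in sorted(idx))
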