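"""Seeded generator of a complete synthetic evaluation world.

Produces a gold standard, domain/GO annotations, a PPI network, a
second-species interaction list with an ortholog map, and protein
sequences -- with controllable planted signal so that training, prediction
and evaluation run end-to-end with no external downloads.  Every planted
feature is recorded in a truth ledger for recovery tests.

Positive and negative gold pairs are both drawn from PPI edges incident to
the E3 set, so a world with all signal knobs at their null settings is
statistically exchangeable between the two classes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayes_engine import EvidenceInputs
from .core_io import (
    AMINO_ACIDS,
    AnnotationMap,
    ESIPair,
    GoldStandard,
    OrthologMap,
    PPINetwork,
    SequenceSet,
    write_gaf,
    write_annotations,
    write_network,
    write_ortholog_map,
    write_pairs,
    write_sequences,
)

logger = logging.getLogger(__name__)

GO_ROOT = "GO:0008150"   # attached to every protein; exercises root exclusion


@dataclass(frozen=True)
class WorldConfig:
    n_e3: int = 60
    n_proteins: int = 400
    n_gsp: int = 200
    n_gsn: int = 600
    n_domains: int = 60
    n_go_terms: int = 80
    #: >= 1; a positive pair carries its E3's planted label pair with
    #: probability 1 - 1/enrichment_strength (1 -> never, i.e. null)
    enrichment_strength: float = 8.0
    label_noise_rate: float = 0.02   # planted labels sprinkled on random proteins
    #: probability of wiring an extra common neighbor onto a positive pair
    loop_boost: float = 0.8
    n_motif_e3s: int = 6
    motif_width: int = 3
    motif_fg_rate: float = 1.0   # insertion rate into a motif E3's substrates
    motif_bg_rate: float = 0.02  # insertion rate into all other sequences
    ortholog_coverage: float = 0.3   # fraction of positives mirrored in mouse
    homolog_noise: float = 0.02      # fraction of negatives mirrored (decoys)
    one_to_many_orthologs: bool = False
    ppi_density: float = 0.1
    seq_length: int = 40
    zipf_exponent: float = 1.6   # skew of E3 usage in the gold set; rare E3s
                                 # populate the C2/C3 partition classes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "motif_fg_rate", "motif_bg_rate", "ortholog_coverage",
            "homolog_noise", "loop_boost", "ppi_density", "label_noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.enrichment_strength < 1.0:
            raise ValueError("enrichment_strength must be >= 1")
        if self.n_gsp > self.n_e3 * self.n_proteins:
            raise ValueError("n_gsp exceeds the number of possible pairs")
        if self.n_e3 >= self.n_proteins:
            raise ValueError("need n_e3 < n_proteins")


@dataclass
class World:
    config: WorldConfig
    gold: GoldStandard
    domain_ann: AnnotationMap
    go_ann: AnnotationMap
    ppi: PPINetwork
    mouse_esis: frozenset[ESIPair]
    omap: OrthologMap
    sequences: SequenceSet
    truth: dict

    def inputs(self) -> EvidenceInputs:
        return EvidenceInputs(
            domain_ann=self.domain_ann,
            go_ann=self.go_ann,
            ppi=self.ppi,
            mouse_esis=self.mouse_esis,
            omap=self.omap,
            sequences=self.sequences,
        )

    @property
    def e3_ids(self) -> list[str]:
        return self.truth["e3_ids"]

    @property
    def protein_ids(self) -> list[str]:
        return self.truth["protein_ids"]


def _er_edges(ids: list[str], density: float, rng: np.random.Generator) -> list[tuple[str, str]]:
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < density
    return [(ids[i], ids[j]) for i, j in zip(iu[mask], ju[mask])]


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _insert_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    if len(seq) <= len(motif):
        return motif
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):]


def generate_world(config: WorldConfig) -> World:
    """Build a fully reproducible synthetic world from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    e3_ids = [f"E{i:04d}" for i in range(1, config.n_e3 + 1)]
    other_ids = [f"P{i:04d}" for i in range(1, config.n_proteins - config.n_e3 + 1)]
    protein_ids = e3_ids + other_ids

    # --- sequences -------------------------------------------------------
    sequences = SequenceSet()
    for pid in protein_ids:
        length = max(20, int(rng.poisson(config.seq_length)))
        sequences[pid] = _random_sequence(length, rng)

    # --- PPI network -----------------------------------------------------
    edges = _er_edges(protein_ids, config.ppi_density, rng)
    ppi = PPINetwork(edges)

    # --- gold standard: both classes drawn from E3-incident edges --------
    eligible_by_e3 = {
        e3: sorted(ppi.neighbors(e3)) for e3 in e3_ids if ppi.neighbors(e3)
    }
    n_eligible = sum(len(v) for v in eligible_by_e3.values())
    if config.n_gsp + config.n_gsn > n_eligible:
        raise ValueError(
            f"world infeasible: {config.n_gsp + config.n_gsn} gold pairs "
            f"requested but only {n_eligible} eligible E3-incident edges"
        )
    # skewed E3 usage among positives so that rarely-used E3s exist (the
    # C3 partition class is empty otherwise)
    weights = {
        e3: 1.0 / (rank + 1) ** config.zipf_exponent
        for rank, e3 in enumerate(sorted(eligible_by_e3))
    }
    # draw the whole gold set with one weighted pass, then split at random:
    # positives and negatives are exchangeable in every respect except the
    # signal planted afterwards, so a null-configured world really is null
    remaining = {e3: list(nbrs) for e3, nbrs in eligible_by_e3.items()}
    drawn: list[ESIPair] = []
    while len(drawn) < config.n_gsp + config.n_gsn:
        avail = sorted(e3 for e3, nbrs in remaining.items() if nbrs)
        if not avail:
            raise ValueError("ran out of eligible pairs while sampling the gold set")
        w = np.array([weights[e3] for e3 in avail])
        e3 = avail[int(rng.choice(len(avail), p=w / w.sum()))]
        nbrs = remaining[e3]
        sub = nbrs.pop(int(rng.integers(0, len(nbrs))))
        if sub != e3:
            drawn.append(ESIPair(e3, sub))
    split = rng.permutation(len(drawn))
    positives = {drawn[i] for i in split[: config.n_gsp]}
    negatives = frozenset(drawn[i] for i in split[config.n_gsp :])
    gold = GoldStandard(frozenset(positives), negatives)
    pos_sorted = sorted(positives)

    # --- annotations with planted label pairs ----------------------------
    def base_annotations(vocab: list[str]) -> dict[str, set[str]]:
        ann: dict[str, set[str]] = {}
        for pid in protein_ids:
            k = 1 + int(rng.poisson(2))
            picks = rng.integers(0, len(vocab), size=k)
            ann[pid] = {vocab[i] for i in picks}
        return ann

    domain_vocab = [f"D{i:04d}" for i in range(1, config.n_domains + 1)]
    go_vocab = [f"GO:{7000000 + i}" for i in range(1, config.n_go_terms + 1)]
    dom_ann = base_annotations(domain_vocab)
    go_ann = base_annotations(go_vocab)
    for pid in protein_ids:
        go_ann[pid].add(GO_ROOT)

    # each E3 owns one planted label pair: its substrates receive the
    # substrate-side label, so the ratio of the pair stays well above 1, the
    # signal is E3-specific (folds that hold out all of an E3's pairs lose
    # it, giving the C2/C3 partition classes genuinely weaker evidence), and
    # the E3-side marginal of a planted label tracks its joint count
    planted_domain_pairs = {e3: (f"DSIG_E_{e3}", f"DSIG_S_{e3}") for e3 in e3_ids}
    planted_go_pairs = {e3: (f"GO:E_{e3}", f"GO:S_{e3}") for e3 in e3_ids}
    p_plant = 1.0 - 1.0 / config.enrichment_strength
    planted_pair_log: list[list[str]] = []
    for pair in pos_sorted:
        if rng.random() < p_plant:
            de, ds = planted_domain_pairs[pair.e3]
            dom_ann[pair.e3].add(de)
            dom_ann[pair.substrate].add(ds)
            ge, gs = planted_go_pairs[pair.e3]
            go_ann[pair.e3].add(ge)
            go_ann[pair.substrate].add(gs)
            planted_pair_log.append([pair.e3, pair.substrate, de, ds, ge, gs])
    # sprinkle planted labels on random proteins so marginals are not
    # exclusively signal-borne
    if config.label_noise_rate > 0 and planted_pair_log:
        all_sig = sorted({lab for row in planted_pair_log for lab in row[2:4]})
        all_sig_go = sorted({lab for row in planted_pair_log for lab in row[4:6]})
        for pid in protein_ids:
            if rng.random() < config.label_noise_rate:
                dom_ann[pid].add(all_sig[int(rng.integers(0, len(all_sig)))])
            if rng.random() < config.label_noise_rate:
                go_ann[pid].add(all_sig_go[int(rng.integers(0, len(all_sig_go)))])

    # --- extra triangles around positive pairs ---------------------------
    boosted: list[list[str]] = []
    if config.loop_boost > 0:
        extra_edges = []
        for pair in pos_sorted:
            if rng.random() < config.loop_boost:
                helper = protein_ids[int(rng.integers(0, len(protein_ids)))]
                if helper in (pair.e3, pair.substrate):
                    continue
                extra_edges.append((pair.e3, helper))
                extra_edges.append((pair.substrate, helper))
                boosted.append([pair.e3, pair.substrate, helper])
        if extra_edges:
            ppi = PPINetwork(ppi.edges() + extra_edges)

    # --- planted motifs --------------------------------------------------
    substrates_of: dict[str, list[str]] = {}
    for pair in pos_sorted:
        substrates_of.setdefault(pair.e3, []).append(pair.substrate)
    busiest = sorted(substrates_of, key=lambda e: (-len(substrates_of[e]), e))
    motif_e3s = busiest[: config.n_motif_e3s]
    planted_motifs: dict[str, str] = {}
    for e3 in motif_e3s:
        motif = "".join(
            AMINO_ACIDS[i]
            for i in rng.integers(0, len(AMINO_ACIDS), size=config.motif_width)
        )
        planted_motifs[e3] = motif
    if config.motif_fg_rate > 0 or config.motif_bg_rate > 0:
        fg_targets: dict[str, list[str]] = {}
        for e3 in motif_e3s:
            for sub in substrates_of[e3]:
                fg_targets.setdefault(sub, []).append(planted_motifs[e3])
        all_motifs = sorted(planted_motifs.values())
        for pid in protein_ids:
            if pid in fg_targets:
                # a substrate serving several motif E3s carries each motif
                for motif in fg_targets[pid]:
                    if rng.random() < config.motif_fg_rate:
                        sequences[pid] = _insert_motif(sequences[pid], motif, rng)
            elif all_motifs and rng.random() < config.motif_bg_rate:
                m = all_motifs[int(rng.integers(0, len(all_motifs)))]
                sequences[pid] = _insert_motif(sequences[pid], m, rng)

    # --- ortholog mirror -------------------------------------------------
    mouse_esis: set[ESIPair] = set()
    omap_map: dict[str, set[str]] = {}
    mirrored: list[list[str]] = []
    if config.ortholog_coverage > 0:
        def mirror(pair: ESIPair) -> None:
            me, ms = f"m_{pair.e3}", f"m_{pair.substrate}"
            mouse_esis.add(ESIPair(me, ms))
            omap_map.setdefault(me, set()).add(pair.e3)
            omap_map.setdefault(ms, set()).add(pair.substrate)
            if config.one_to_many_orthologs:
                # map the mouse substrate onto a second human protein too
                alt = protein_ids[int(rng.integers(0, len(protein_ids)))]
                omap_map[ms].add(alt)

        for pair in pos_sorted:
            if rng.random() < config.ortholog_coverage:
                mirror(pair)
                mirrored.append([pair.e3, pair.substrate])
        for pair in sorted(negatives):
            if rng.random() < config.homolog_noise:
                mirror(pair)

    truth = {
        "e3_ids": e3_ids,
        "protein_ids": protein_ids,
        "planted_domain_pairs": {e3: list(p) for e3, p in planted_domain_pairs.items()},
        "planted_go_pairs": {e3: list(p) for e3, p in planted_go_pairs.items()},
        "planted_positive_labels": planted_pair_log,
        "boosted_triangles": boosted,
        "planted_motifs": planted_motifs,
        "mirrored_positives": mirrored,
    }
    return World(
        config=config,
        gold=gold,
        domain_ann=AnnotationMap(
            "domain", {p: frozenset(ls) for p, ls in dom_ann.items()}
        ),
        go_ann=AnnotationMap("go", {p: frozenset(ls) for p, ls in go_ann.items()}),
        ppi=ppi,
        mouse_esis=frozenset(mouse_esis),
        omap=OrthologMap({s: frozenset(t) for s, t in omap_map.items()}),
        sequences=sequences,
        truth=truth,
    )


def world_to_files(world: World, out_dir: str | Path) -> dict[str, Path]:
    """Serialize the world in the exact dialects the loaders read.

    Returns the mapping of logical name -> written path.  ``gsn.tsv`` is
    omitted (and flagged in the log) when the world has no negatives.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, fname: str, writer, *args) -> None:
        path = out / fname
        writer(*args, path)
        written[name] = path

    emit("gsp", "gsp.tsv", write_pairs, world.gold.positives)
    if world.gold.negatives:
        emit("gsn", "gsn.tsv", write_pairs, world.gold.negatives)
    else:
        logger.warning("world has no negatives; gsn.tsv not written")
    emit("domains", "domains.tsv", write_annotations, world.domain_ann)
    emit("go", "go.gaf", write_gaf, world.go_ann)
    emit("ppi", "ppi.tsv", write_network, world.ppi)
    emit("orthologs", "orthologs.tsv", write_ortholog_map, world.omap)
    if world.mouse_esis:
        emit("mouse_esi", "mouse_esi.tsv", write_pairs, world.mouse_esis)
    emit("proteome", "proteome.fasta", write_sequences, world.sequences)

    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(world.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["truth"] = truth_path

    config_path = out / "world.json"
    with open(config_path, "w") as fh:
        json.dump(dataclasses.asdict(world.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["config"] = config_path
    return written


def null_config(seed: int = 0, **overrides) -> WorldConfig:
    """A world with every signal knob at its null setting."""
    base = dict(
        enrichment_strength=1.0,
        loop_boost=0.0,
        motif_fg_rate=0.02,
        motif_bg_rate=0.02,
        ortholog_coverage=0.0,
        seed=seed,
    )
    base.update(overrides)
    return WorldConfig(**base)
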