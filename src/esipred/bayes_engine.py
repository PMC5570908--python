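"""Likelihood-ratio calibration and naive-Bayes evidence integration.

Each evidence type is calibrated into a binned likelihood-ratio table
against the gold-standard positive/negative sets: per bin,
``LR = (TP_f / T) / (FP_f / F)`` with an optional pseudocount.  Evidence
types trained on the positive set itself (annotation-pair enrichment and
motifs) are calibrated with a repeated 2/3-train / 1/3-holdout protocol to
avoid self-scoring; network topology and ortholog transfer are external and
calibrated directly.

At prediction time each type contributes the *maximum* LR over its firing
features, types are combined by multiplication (conditional independence),
and the composite LR is squashed to a confidence score
``1 / (1 + exp(-log10(LR_comp)))`` in (0, 1), 0.5 = uninformative.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np

from .config import ModelConfig
from .core_io import (
    AnnotationMap,
    ESIPair,
    GoldStandard,
    OrthologMap,
    PPINetwork,
)
from .evidence import (
    EnrichmentFeature,
    Motif,
    count_loops,
    discover_motifs,
    enriched_pair_table,
    homology_support,
    match_enrichment,
    match_motif,
    pattern_from_string,
)

EVIDENCE_TYPES = ("homology", "domain", "go", "network_n3", "network_n4", "motif")

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# LR tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class LRBin:
    lo: float
    hi: float
    tp_f: int
    fp_f: int
    lr: float


@dataclass(frozen=True)
class LRTable:
    """Binned likelihood-ratio lookup over one evidence type's feature axis."""

    evidence_type: str
    bins: tuple[LRBin, ...]
    smoothing: float

    def lookup(self, value: float) -> float:
        for b in self.bins:
            if b.lo <= value < b.hi:
                return b.lr
        raise ValueError(
            f"feature value {value} outside the {self.evidence_type} table range"
        )


def estimate_lr_table(
    pos_features: Sequence[float],
    neg_features: Sequence[float],
    bin_edges: Sequence[float],
    smoothing: float = 1.0,
    *,
    evidence_type: str = "feature",
    t_total: int | None = None,
    f_total: int | None = None,
    lr_cap: tuple[float, float] = (1e-3, 1e3),
) -> LRTable:
    """Binned LR estimate ``((tp+s)/(T+s)) / ((fp+s)/(F+s))`` per bin.

    ``t_total`` / ``f_total`` default to the feature-list lengths; pass them
    explicitly when some gold pairs exhibit no feature at all (those pairs
    count toward T/F but fall in no bin).  Bins with ``tp = fp = 0`` get
    LR = 1; all LRs are clamped to ``lr_cap``.
    """
    edges = [float(e) for e in bin_edges]
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    t = len(pos_features) if t_total is None else t_total
    f = len(neg_features) if f_total is None else f_total
    if t <= 0 or f <= 0:
        raise ValueError("need positive T and F counts")
    s = float(smoothing)
    lo_cap, hi_cap = lr_cap
    bins = []
    for lo, hi in zip(edges, edges[1:]):
        tp = sum(1 for v in pos_features if lo <= v < hi)
        fp = sum(1 for v in neg_features if lo <= v < hi)
        if tp == 0 and fp == 0:
            lr = 1.0
        else:
            num = (tp + s) / (t + s)
            den = (fp + s) / (f + s)
            lr = math.inf if den == 0.0 else num / den
        lr = min(max(lr, lo_cap), hi_cap)
        bins.append(LRBin(lo, hi, tp, fp, lr))
    return LRTable(evidence_type, tuple(bins), s)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class PriorModel:
    p_positive: float
    o_prior: float

    @classmethod
    def from_counts(cls, t: int, f: int) -> "PriorModel":
        if t <= 0 or f <= 0:
            raise ValueError("need T > 0 and F > 0 to estimate the prior")
        p = t / (t + f)
        return cls(p, p / (1.0 - p))


@dataclass(frozen=True)
class EvidenceInputs:
    """The raw evidence sources a trained model is applied against."""

    domain_ann: AnnotationMap | None = None
    go_ann: AnnotationMap | None = None
    ppi: PPINetwork | None = None
    mouse_esis: frozenset[ESIPair] = frozenset()
    omap: OrthologMap = field(default_factory=OrthologMap)
    sequences: Mapping[str, str] = field(default_factory=dict)


@dataclass
class TrainedModel:
    config: ModelConfig
    prior: PriorModel
    enriched: dict[str, dict[tuple[str, str], EnrichmentFeature]]
    motifs: dict[str, list[Motif]]
    lr_tables: dict[str, LRTable]
    fingerprint: str


def _pair_fingerprint(gold: GoldStandard) -> str:
    h = hashlib.sha256()
    for label, pairs in (("+", gold.positives), ("-", gold.negatives)):
        for p in sorted(pairs):
            h.update(f"{label}{p.e3}\t{p.substrate}\n".encode())
    return h.hexdigest()


def pair_set_fingerprint(pairs: Iterable[ESIPair]) -> str:
    """Digest of an ordered-pair set; used for leakage audits in evaluation."""
    h = hashlib.sha256()
    for p in sorted(pairs):
        h.update(f"{p.e3}\t{p.substrate}\n".encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# per-type feature extraction
# ---------------------------------------------------------------------------


def _domain_feature(
    pair: ESIPair,
    table: Mapping[tuple[str, str], EnrichmentFeature],
    ann: AnnotationMap | None,
) -> float | None:
    if ann is None:
        return None
    hits = match_enrichment(pair, table, ann)
    if not hits:
        return None
    return max(h.ratio for h in hits)


def _motif_feature(
    pair: ESIPair,
    motifs: Mapping[str, list[Motif]],
    sequences: Mapping[str, str],
) -> float | None:
    seq = sequences.get(pair.substrate)
    if seq is None:
        return None
    scores = [m.motif_score for m in motifs.get(pair.e3, []) if match_motif(seq, m)]
    return max(scores) if scores else None


def _network_features(
    pair: ESIPair, ppi: PPINetwork | None
) -> tuple[float | None, float | None]:
    if ppi is None or pair.e3 not in ppi or pair.substrate not in ppi:
        return None, None
    loops = count_loops(pair, ppi)
    return float(loops.n3), float(loops.n4)


def _homology_feature(pair: ESIPair, inputs: EvidenceInputs) -> float | None:
    ev = homology_support(pair, inputs.mouse_esis, inputs.omap)
    return 1.0 if ev.supported else None


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _split_thirds(
    pairs: Sequence[ESIPair], split: float, rng: np.random.Generator
) -> tuple[list[ESIPair], list[ESIPair]]:
    order = list(pairs)
    perm = rng.permutation(len(order))
    n_train = int(round(split * len(order)))
    n_train = min(max(n_train, 1), len(order) - 1)
    train = [order[i] for i in perm[:n_train]]
    holdout = [order[i] for i in perm[n_train:]]
    return train, holdout


def _calibrate_heldout(
    gsp: Sequence[ESIPair],
    gsn: Sequence[ESIPair],
    builder: Callable[[Sequence[ESIPair]], Callable[[ESIPair], float | None]],
    config: ModelConfig,
    evidence_type: str,
    seed: int,
) -> LRTable:
    """Repeated split calibration for evidence trained on the positive set.

    Per repeat a feature scorer is built from the 2/3 train split; features of
    the held-out positives and of every negative are pooled across repeats
    before the LR estimate.
    """
    rng = np.random.default_rng(seed)
    pos_feats: list[float] = []
    neg_feats: list[float] = []
    t_total = 0
    f_total = 0
    for _ in range(config.calibration_repeats):
        train, holdout = _split_thirds(gsp, config.calibration_split, rng)
        scorer = builder(train)
        for pair in holdout:
            v = scorer(pair)
            if v is not None:
                pos_feats.append(v)
        t_total += len(holdout)
        for pair in gsn:
            v = scorer(pair)
            if v is not None:
                neg_feats.append(v)
        f_total += len(gsn)
    return estimate_lr_table(
        pos_feats,
        neg_feats,
        config.bin_edges[evidence_type],
        config.smoothing,
        evidence_type=evidence_type,
        t_total=t_total,
        f_total=f_total,
        lr_cap=config.lr_cap,
    )


def _direct_calibration(
    gsp: Sequence[ESIPair],
    gsn: Sequence[ESIPair],
    scorer: Callable[[ESIPair], float | None],
    config: ModelConfig,
    evidence_type: str,
) -> LRTable:
    pos = [v for v in (scorer(p) for p in gsp) if v is not None]
    neg = [v for v in (scorer(p) for p in gsn) if v is not None]
    return estimate_lr_table(
        pos,
        neg,
        config.bin_edges[evidence_type],
        config.smoothing,
        evidence_type=evidence_type,
        t_total=len(gsp),
        f_total=len(gsn),
        lr_cap=config.lr_cap,
    )


def _enrichment_builder(
    ann: AnnotationMap, config: ModelConfig
) -> Callable[[Sequence[ESIPair]], Callable[[ESIPair], float | None]]:
    exclude = (
        frozenset(config.go_root_terms)
        if ann.namespace == "go" and config.exclude_go_roots
        else frozenset()
    )

    def build(train: Sequence[ESIPair]) -> Callable[[ESIPair], float | None]:
        table = enriched_pair_table(
            train, ann, config.min_enrichment_ratio, exclude_labels=exclude,
            min_support=config.min_enrichment_support,
        )
        return lambda pair: _domain_feature(pair, table, ann)

    return build


def _train_motifs(
    train: Sequence[ESIPair], inputs: EvidenceInputs, config: ModelConfig
) -> dict[str, list[Motif]]:
    """Discover motifs per E3 from its training substrates, with the E3's PPI
    interactors as background.  Known substrates are excluded from the
    background, otherwise a genuine recognition motif would inflate its own
    background frequency."""
    assert inputs.ppi is not None
    by_e3: dict[str, list[str]] = {}
    for pair in train:
        by_e3.setdefault(pair.e3, []).append(pair.substrate)
    motifs: dict[str, list[Motif]] = {}
    for e3 in sorted(by_e3):
        substrates = set(by_e3[e3])
        fg = {
            s: inputs.sequences[s]
            for s in sorted(substrates)
            if s in inputs.sequences
        }
        if len(fg) < config.motif.min_fg:
            continue
        bg = {
            p: inputs.sequences[p]
            for p in sorted(inputs.ppi.neighbors(e3))
            if p in inputs.sequences and p != e3 and p not in substrates
        }
        if not bg:
            continue
        found = discover_motifs(e3, fg, bg, config.motif)
        if found:
            motifs[e3] = found
    return motifs


def _motif_builder(
    inputs: EvidenceInputs, config: ModelConfig
) -> Callable[[Sequence[ESIPair]], Callable[[ESIPair], float | None]]:
    def build(train: Sequence[ESIPair]) -> Callable[[ESIPair], float | None]:
        motifs = _train_motifs(train, inputs, config)
        return lambda pair: _motif_feature(pair, motifs, inputs.sequences)

    return build


def calibrate_enrichment_lr(
    gsp: Iterable[ESIPair],
    gsn: Iterable[ESIPair],
    ann: AnnotationMap,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], EnrichmentFeature], LRTable]:
    """Repeated 2/3-train / 1/3-holdout LR calibration for one annotation
    namespace, plus the final enrichment table rebuilt on the full positive
    set.  The held-out feature of a pair is its maximum matching ratio."""
    config = config or ModelConfig()
    gsp = sorted(set(gsp))
    gsn = sorted(set(gsn))
    evidence_type = "domain" if ann.namespace == "domain" else "go"
    table_lr = _calibrate_heldout(
        gsp, gsn, _enrichment_builder(ann, config), config, evidence_type, seed=seed
    )
    exclude = (
        frozenset(config.go_root_terms)
        if ann.namespace == "go" and config.exclude_go_roots
        else frozenset()
    )
    full_table = enriched_pair_table(
        gsp, ann, config.min_enrichment_ratio, exclude_labels=exclude,
        min_support=config.min_enrichment_support,
    )
    return full_table, table_lr


def train_model(
    gold: GoldStandard,
    inputs: EvidenceInputs,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit all evidence tables and LR tables against a gold standard.

    Enrichment (domain/GO) and motif evidence use the repeated-holdout
    calibration; network loops and ortholog transfer are calibrated directly.
    The final enrichment tables and motif sets are rebuilt on the full
    positive set.
    """
    config = config or ModelConfig()
    gold.require_nonempty()
    gsp = sorted(gold.positives)
    gsn = sorted(gold.negatives)
    lr_tables: dict[str, LRTable] = {}
    enriched: dict[str, dict[tuple[str, str], EnrichmentFeature]] = {}

    for evidence_type, ann in (("domain", inputs.domain_ann), ("go", inputs.go_ann)):
        if ann is None:
            continue
        enriched[evidence_type], lr_tables[evidence_type] = calibrate_enrichment_lr(
            gsp, gsn, ann, config, seed=seed
        )

    motifs: dict[str, list[Motif]] = {}
    if inputs.ppi is not None and inputs.sequences:
        lr_tables["motif"] = _calibrate_heldout(
            gsp, gsn, _motif_builder(inputs, config), config, "motif", seed=seed + 1
        )
        motifs = _train_motifs(gsp, inputs, config)

    if inputs.ppi is not None:
        lr_tables["network_n3"] = _direct_calibration(
            gsp, gsn, lambda p: _network_features(p, inputs.ppi)[0], config,
            "network_n3",
        )
        lr_tables["network_n4"] = _direct_calibration(
            gsp, gsn, lambda p: _network_features(p, inputs.ppi)[1], config,
            "network_n4",
        )

    if inputs.mouse_esis:
        lr_tables["homology"] = _direct_calibration(
            gsp, gsn, lambda p: _homology_feature(p, inputs), config, "homology"
        )

    return TrainedModel(
        config=config,
        prior=PriorModel.from_counts(gold.t, gold.f),
        enriched=enriched,
        motifs=motifs,
        lr_tables=lr_tables,
        fingerprint=_pair_fingerprint(gold),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prediction:
    pair: ESIPair
    per_type_lr: Mapping[str, float]
    lr_comp: float
    o_post: float
    score: float
    supporting_features: tuple[str, ...] = ()


def evidence_lr(
    pair: ESIPair, model: TrainedModel, inputs: EvidenceInputs
) -> dict[str, float]:
    """Maximum LR per evidence type over all firing features; silent types
    are omitted (treated as LR = 1 downstream)."""
    out: dict[str, float] = {}

    def put(evidence_type: str, values: Iterable[float]) -> None:
        table = model.lr_tables.get(evidence_type)
        if table is None:
            return
        lrs = [table.lookup(v) for v in values]
        if lrs:
            out[evidence_type] = max(lrs)

    if inputs.domain_ann is not None and "domain" in model.enriched:
        hits = match_enrichment(pair, model.enriched["domain"], inputs.domain_ann)
        put("domain", (h.ratio for h in hits))
    if inputs.go_ann is not None and "go" in model.enriched:
        hits = match_enrichment(pair, model.enriched["go"], inputs.go_ann)
        put("go", (h.ratio for h in hits))

    n3, n4 = _network_features(pair, inputs.ppi)
    if n3 is not None:
        put("network_n3", (n3,))
    if n4 is not None:
        put("network_n4", (n4,))

    mscore = _motif_feature(pair, model.motifs, inputs.sequences)
    if mscore is not None:
        put("motif", (mscore,))

    if _homology_feature(pair, inputs) is not None:
        put("homology", (1.0,))

    return out


def combine(per_type_lr: Mapping[str, float]) -> float:
    """Naive-Bayes product of per-type LRs; the empty map combines to 1."""
    lr_comp = 1.0
    for evidence_type, lr in per_type_lr.items():
        if lr <= 0:
            raise ValueError(f"non-positive LR for {evidence_type}: {lr}")
        lr_comp *= lr
    return lr_comp


def prior_and_posterior(
    gold: GoldStandard, lr_comp: float
) -> tuple[PriorModel, float]:
    prior = PriorModel.from_counts(gold.t, gold.f)
    return prior, prior.o_prior * lr_comp


def confidence_score(lr_comp: float) -> float:
    """Squash a composite LR to (0, 1): ``1 / (1 + exp(-log10(lr_comp)))``.

    Base 10 keeps the published worked value (LR 195.79 -> 0.908); with a
    natural log the same formula would collapse to LR/(1+LR) = 0.995.
    """
    if lr_comp <= 0:
        raise ValueError("lr_comp must be > 0")
    return 1.0 / (1.0 + math.exp(-math.log10(lr_comp)))


def _supporting_features(
    pair: ESIPair, model: TrainedModel, inputs: EvidenceInputs
) -> tuple[str, ...]:
    notes: list[str] = []
    if inputs.domain_ann is not None and "domain" in model.enriched:
        for h in match_enrichment(pair, model.enriched["domain"], inputs.domain_ann):
            notes.append(f"domain:{h.label_e3}~{h.label_sub}:ratio={h.ratio:.3g}")
    if inputs.go_ann is not None and "go" in model.enriched:
        for h in match_enrichment(pair, model.enriched["go"], inputs.go_ann):
            notes.append(f"go:{h.label_e3}~{h.label_sub}:ratio={h.ratio:.3g}")
    n3, n4 = _network_features(pair, inputs.ppi)
    if n3 is not None:
        notes.append(f"network:n3={int(n3)}:n4={int(n4)}")
    seq = inputs.sequences.get(pair.substrate)
    if seq is not None:
        for m in model.motifs.get(pair.e3, []):
            if match_motif(seq, m):
                notes.append(f"motif:{m}:score={m.motif_score:.2f}")
    ev = homology_support(pair, inputs.mouse_esis, inputs.omap)
    if ev.supported and ev.source_pair is not None:
        notes.append(f"homology:{ev.source_pair.e3}~{ev.source_pair.substrate}")
    return tuple(notes)


def predict(
    pair: ESIPair,
    model: TrainedModel,
    inputs: EvidenceInputs,
    *,
    with_provenance: bool = True,
) -> Prediction:
    per_type = evidence_lr(pair, model, inputs)
    lr_comp = combine(per_type)
    o_post = model.prior.o_prior * lr_comp
    support = (
        _supporting_features(pair, model, inputs) if with_provenance else ()
    )
    return Prediction(
        pair=pair,
        per_type_lr=per_type,
        lr_comp=lr_comp,
        o_post=o_post,
        score=confidence_score(lr_comp),
        supporting_features=support,
    )


# ---------------------------------------------------------------------------
# proteome scan
# ---------------------------------------------------------------------------


def enumerate_scan_pairs(
    e3_list: Sequence[str],
    proteome: Sequence[str],
    *,
    include_self: bool = False,
) -> Iterator[tuple[str, str]]:
    """Lazily enumerate every ordered (E3, protein) pair; self pairs are
    skipped unless ``include_self``."""
    for e3 in e3_list:
        for prot in proteome:
            if e3 == prot and not include_self:
                continue
            yield e3, prot


@dataclass
class ScanResult:
    predictions: list[Prediction]
    n_enumerated: int
    n_self_excluded: int


def proteome_scan(
    e3_list: Iterable[str],
    proteome: Iterable[str],
    model: TrainedModel,
    inputs: EvidenceInputs,
    min_score: float = 0.0,
    *,
    include_self: bool = False,
) -> ScanResult:
    """Score every ordered (E3, protein) pair and keep those above min_score.

    Streaming: memory scales with the number of *emitted* predictions, not
    with the pair count.  Output is sorted by score descending with a
    deterministic (e3, substrate) tie-break.
    """
    e3s = sorted(set(e3_list))
    prots = sorted(set(proteome))
    if not e3s or not prots:
        raise ValueError("e3_list and proteome must be non-empty")
    kept: list[Prediction] = []
    n_enum = 0
    n_self = 0
    for e3, prot in enumerate_scan_pairs(e3s, prots, include_self=True):
        if e3 == prot and not include_self:
            n_self += 1
            continue
        n_enum += 1
        pred = predict(
            ESIPair(e3, prot, self_interaction=(e3 == prot)),
            model,
            inputs,
            with_provenance=False,
        )
        if pred.score >= min_score:
            kept.append(pred)
    kept.sort(key=lambda p: (-p.score, p.pair.e3, p.pair.substrate))
    return ScanResult(kept, n_enum, n_self)


# ---------------------------------------------------------------------------
# model archive (directory of human-readable TSV + JSON manifest)
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the model as a versioned directory of TSV tables + manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": model.config.to_dict(),
        "prior": {"p_positive": model.prior.p_positive, "o_prior": model.prior.o_prior},
        "fingerprint": model.fingerprint,
        "evidence_types": sorted(model.lr_tables),
    }
    with open(path / "model.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(path / "lr_tables.tsv", "w") as fh:
        fh.write("evidence_type\tlo\thi\ttp_f\tfp_f\tlr\tsmoothing\n")
        for etype in sorted(model.lr_tables):
            table = model.lr_tables[etype]
            for b in table.bins:
                fh.write(
                    f"{etype}\t{_fmt(b.lo)}\t{_fmt(b.hi)}\t{b.tp_f}\t{b.fp_f}"
                    f"\t{_fmt(b.lr)}\t{_fmt(table.smoothing)}\n"
                )
    for namespace in ("domain", "go"):
        table = model.enriched.get(namespace, {})
        with open(path / f"enriched_{namespace}.tsv", "w") as fh:
            fh.write("label_e3\tlabel_sub\tratio\tsupport\n")
            for key in sorted(table):
                feat = table[key]
                fh.write(
                    f"{feat.label_e3}\t{feat.label_sub}\t{_fmt(feat.ratio)}"
                    f"\t{feat.support}\n"
                )
    with open(path / "motifs.tsv", "w") as fh:
        fh.write(
            "e3\tpattern\tmotif_score\tfg_hits\tfg_total\tbg_hits\tbg_total\n"
        )
        for e3 in sorted(model.motifs):
            for m in model.motifs[e3]:
                fh.write(
                    f"{e3}\t{m}\t{_fmt(m.motif_score)}\t{m.fg_hits}\t{m.fg_total}"
                    f"\t{m.bg_hits}\t{m.bg_total}\n"
                )


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    with open(path / "model.json") as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {manifest.get('schema_version')!r}"
        )
    config = ModelConfig.from_dict(manifest["config"])
    prior = PriorModel(**manifest["prior"])

    lr_rows: dict[str, list[LRBin]] = {}
    smoothings: dict[str, float] = {}
    with open(path / "lr_tables.tsv") as fh:
        next(fh)
        for line in fh:
            etype, lo, hi, tp, fp, lr, s = line.rstrip("\n").split("\t")
            lr_rows.setdefault(etype, []).append(
                LRBin(float(lo), float(hi), int(tp), int(fp), float(lr))
            )
            smoothings[etype] = float(s)
    lr_tables = {
        etype: LRTable(etype, tuple(bins), smoothings[etype])
        for etype, bins in lr_rows.items()
    }

    enriched: dict[str, dict[tuple[str, str], EnrichmentFeature]] = {}
    for namespace in ("domain", "go"):
        fpath = path / f"enriched_{namespace}.tsv"
        if not fpath.exists():
            continue
        table: dict[tuple[str, str], EnrichmentFeature] = {}
        with open(fpath) as fh:
            next(fh)
            for line in fh:
                le, ls, ratio, support = line.rstrip("\n").split("\t")
                table[(le, ls)] = EnrichmentFeature(le, ls, float(ratio), int(support))
        if table:
            enriched[namespace] = table

    motifs: dict[str, list[Motif]] = {}
    mpath = path / "motifs.tsv"
    if mpath.exists():
        with open(mpath) as fh:
            next(fh)
            for line in fh:
                e3, pat, score, fgh, fgt, bgh, bgt = line.rstrip("\n").split("\t")
                motifs.setdefault(e3, []).append(
                    Motif(
                        e3,
                        pattern_from_string(pat),
                        float(score),
                        int(fgh),
                        int(fgt),
                        int(bgh),
                        int(bgt),
                    )
                )

    return TrainedModel(
        config=config,
        prior=prior,
        enriched=enriched,
        motifs=motifs,
        lr_tables=lr_tables,
        fingerprint=manifest["fingerprint"],
    )
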