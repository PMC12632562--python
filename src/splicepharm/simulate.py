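"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator draws from its own RNG stream, derived from the master seed
by a stable text label, so adding a new output never perturbs the others.
The junction-count model is deliberately simple: inclusion evidence per
event is Binomial(depth, psi) — downstream statistics only ever see
inclusion/exclusion read pairs, so no read-assignment model over isoform
lengths is simulated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_CLASSES = ("CE", "RI", "MXE", "A5SS", "A3SS")
# cassette exons dominate observed differential-splicing catalogs; the
# remaining classes are minor
_CLASS_WEIGHTS = (0.55, 0.15, 0.10, 0.10, 0.10)

MOTIF_LEN = 4


def _stream(master_seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label RNG stream from the master seed."""
    digest = hashlib.sha256(f"{master_seed}/{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the study design being emulated: one RNA library per
    clone condition, junction depth of a few hundred reads per event, a
    five-point 0.001-10 uM dilution series read out in triplicate, and
    amplicon genotyping at depth of a few thousand.
    """

    n_events: int = 200
    psi_base: tuple[float, float] = (0.3, 0.7)  # per-event base drawn uniform
    delta_psi: float = 0.3
    fraction_true: float = 0.5
    read_depth: float = 200.0
    n_samples_per_condition: int = 1
    # expected planted motifs per exon (CCNG in increased-set exons, GGNG in
    # decreased-set exons); 3.5 on a 120 nt exon is roughly twice the
    # uniform-background class rate, i.e. ~3x background in total
    motif_rate_increased: float = 3.5
    motif_rate_decreased: float = 3.5
    exon_len: int = 120
    flank_len: int = 100
    dr_params: dict = field(
        default_factory=lambda: {"top": 1.0, "bottom": 0.05, "ec50": 1e-7, "hill": 1.0}
    )
    concentrations: tuple[float, ...] = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5)  # molar
    n_replicates: int = 3
    n_dmso_wells: int = 6
    noise_sd: float = 0.02
    vaf_true: tuple[float, ...] = (0.0, 1 / 3, 2 / 3, 1.0)
    amplicon_depth: int = 5000
    seed: int = 0

    def validate(self) -> None:
        for name in ("fraction_true",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = (self.psi_base if isinstance(self.psi_base, tuple)
                  else (self.psi_base, self.psi_base))
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"psi_base must lie in [0, 1], got {self.psi_base}")
        if not -1.0 <= self.delta_psi <= 1.0:
            raise ValueError(f"delta_psi must be in [-1, 1], got {self.delta_psi}")
        for v in self.vaf_true:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"vaf_true entries must be in [0, 1], got {v}")
        if self.read_depth <= 0:
            raise ValueError(f"read_depth must be > 0, got {self.read_depth}")
        if self.amplicon_depth <= 0:
            raise ValueError(f"amplicon_depth must be > 0, got {self.amplicon_depth}")
        if self.exon_len < 8:
            raise ValueError(f"exon_len must be >= 8, got {self.exon_len}")
        capacity = self.exon_len // MOTIF_LEN
        for name in ("motif_rate_increased", "motif_rate_decreased"):
            rate = getattr(self, name)
            if rate < 0:
                raise ValueError(f"{name} must be >= 0, got {rate}")
            if rate > capacity:
                raise ValueError(
                    f"{name}={rate} implies more motifs than fit without overlap "
                    f"in a {self.exon_len} nt exon (capacity {capacity})"
                )
        if len(self.concentrations) < 4:
            raise ValueError("need at least 4 concentrations")
        if any(b >= a for a, b in zip(self.concentrations[1:], self.concentrations)):
            raise ValueError("concentrations must be strictly ascending")
        if self.dr_params.get("hill", 1.0) == 0:
            raise ValueError("hill = 0 is a degenerate dose-response curve")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_samples_per_condition < 1 or self.n_events < 1:
            raise ValueError("n_events and n_samples_per_condition must be >= 1")


@dataclass
class TruthTable:
    """Planted ground truth, one entry per generated record."""

    events: dict = field(default_factory=dict)       # event id -> {delta_psi, class, psi_wt}
    exons: dict = field(default_factory=dict)        # exon id -> {label, planted: {variant: n}}
    curves: dict = field(default_factory=dict)       # curve id -> {ec50, hill, top, bottom, ...}
    samples: dict = field(default_factory=dict)      # sample id -> {vaf}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# splicing arm


def gen_splicing_dataset(cfg: SimConfig):
    """Simulate events, per-sample junction counts, and the truth table.

    Returns (events DataFrame, counts DataFrame, TruthTable).  Inclusion
    reads per event/sample are Binomial(depth, psi) with depth drawn
    Poisson(read_depth); exclusion = depth - inclusion.  "True" events get
    psi_mut = clip(psi_wt + delta, 0, 1) with delta = +/- cfg.delta_psi.
    """
    cfg.validate()
    rng = _stream(cfg.seed, "splicing")
    n = cfg.n_events
    ids = [f"E{i:05d}" for i in range(1, n + 1)]
    classes = rng.choice(EVENT_CLASSES, size=n, p=_CLASS_WEIGHTS)
    lo, hi = (cfg.psi_base if isinstance(cfg.psi_base, tuple)
              else (cfg.psi_base, cfg.psi_base))
    psi_wt = rng.uniform(lo, hi, size=n)

    n_true = int(round(cfg.fraction_true * n))
    is_true = np.zeros(n, dtype=bool)
    is_true[rng.choice(n, size=n_true, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n)
    psi_mut = np.where(
        is_true, np.clip(psi_wt + signs * cfg.delta_psi, 0.0, 1.0), psi_wt
    )

    # toy genomic coordinates: events spaced along one contig
    starts = 1000 + 10_000 * np.arange(n)
    events = pd.DataFrame(
        {
            "event_id": ids,
            "gene": [f"GENE{i:05d}" for i in range(1, n + 1)],
            "event_class": classes,
            "chrom": "chrS",
            "start": starts,
            "end": starts + cfg.exon_len,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
        }
    )

    samples = [f"wt_{j+1}" for j in range(cfg.n_samples_per_condition)] + [
        f"mut_{j+1}" for j in range(cfg.n_samples_per_condition)
    ]
    conditions = ["wt"] * cfg.n_samples_per_condition + [
        "mut"
    ] * cfg.n_samples_per_condition

    rows = []
    for sample, cond in zip(samples, conditions):
        psi = psi_wt if cond == "wt" else psi_mut
        depth = rng.poisson(cfg.read_depth, size=n)
        incl = rng.binomial(depth, psi)
        for i in range(n):
            rows.append((ids[i], sample, cond, int(incl[i]), int(depth[i] - incl[i])))
    counts = pd.DataFrame(
        rows, columns=["event_id", "sample_id", "condition", "inclusion_reads", "exclusion_reads"]
    )

    truth = TruthTable()
    for i, eid in enumerate(ids):
        truth.events[eid] = {
            "delta_psi": float(psi_mut[i] - psi_wt[i]),
            "is_true": bool(is_true[i]),
            "event_class": str(classes[i]),
            "psi_wt": float(psi_wt[i]),
        }
    return events, counts, truth


# ---------------------------------------------------------------------------
# sequence arm

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _plant(seq: np.ndarray, k: int, lo: int, hi: int, variants: list[str],
           rng: np.random.Generator, exon_id: str) -> dict[str, int]:
    """Plant k non-overlapping motifs with starts in [lo, hi); returns counts."""
    capacity = (hi - lo) // MOTIF_LEN
    if k > capacity:
        k = capacity  # Poisson tail clamped; realized count is what is recorded
    placed: list[int] = []
    counts: dict[str, int] = {}
    tries = 0
    while len(placed) < k:
        tries += 1
        if tries > 1000 * max(k, 1):
            raise RuntimeError(
                f"could not place {k} non-overlapping motifs in exon {exon_id}"
            )
        pos = int(rng.integers(lo, hi - MOTIF_LEN + 1))
        if any(abs(pos - p) < MOTIF_LEN for p in placed):
            continue
        motif = variants[int(rng.integers(len(variants)))]
        seq[pos:pos + MOTIF_LEN] = np.frombuffer(motif.encode(), dtype="S1")
        placed.append(pos)
        counts[motif] = counts.get(motif, 0) + 1
    return counts


def gen_exon_sequences(events: pd.DataFrame, truth: TruthTable, cfg: SimConfig):
    """Exon+flank sequences with CCNG planted in increased-inclusion exons
    and GGNG in decreased-inclusion exons.

    Returns (records, truth) where records is a list of dicts with keys
    exon_id, sequence, exon_start, exon_end.  Background is uniform A/C/G/T;
    planted motifs sit strictly inside the exon interval and never overlap
    one another.  Null events receive background sequence only.
    """
    cfg.validate()
    rng = _stream(cfg.seed, "sequences")
    ccng = ["CC" + n + "G" for n in "ACGT"]
    ggng = ["GG" + n + "G" for n in "ACGT"]
    total_len = cfg.exon_len + 2 * cfg.flank_len
    exon_start, exon_end = cfg.flank_len, cfg.flank_len + cfg.exon_len

    records = []
    for eid in events["event_id"]:
        info = truth.events.get(eid, {"delta_psi": 0.0})
        d = info["delta_psi"]
        label = "increased" if d > 0 else ("decreased" if d < 0 else "null")
        seq = rng.choice(_BASES, size=total_len)
        planted: dict[str, int] = {}
        if label == "increased" and cfg.motif_rate_increased > 0:
            k = int(rng.poisson(cfg.motif_rate_increased))
            planted = _plant(seq, k, exon_start, exon_end, ccng, rng, eid)
        elif label == "decreased" and cfg.motif_rate_decreased > 0:
            k = int(rng.poisson(cfg.motif_rate_decreased))
            planted = _plant(seq, k, exon_start, exon_end, ggng, rng, eid)
        records.append(
            {
                "exon_id": eid,
                "sequence": seq.tobytes().decode(),
                "exon_start": exon_start,
                "exon_end": exon_end,
            }
        )
        truth.exons[eid] = {"label": label, "planted": planted}
    return records, truth


def gen_motif_sets(n_per_set: int, cfg: SimConfig):
    """Two labeled exon-sequence sets (increased/decreased) without running
    the splicing arm; convenience for the motif-enrichment stage."""
    events = pd.DataFrame(
        {"event_id": [f"X{i:05d}" for i in range(1, 2 * n_per_set + 1)]}
    )
    truth = TruthTable()
    for i, eid in enumerate(events["event_id"]):
        truth.events[eid] = {"delta_psi": 0.3 if i < n_per_set else -0.3}
    records, truth = gen_exon_sequences(events, truth, cfg)
    inc = [r for r in records if truth.exons[r["exon_id"]]["label"] == "increased"]
    dec = [r for r in records if truth.exons[r["exon_id"]]["label"] == "decreased"]
    return inc, dec, truth


# ---------------------------------------------------------------------------
# pharmacology arm


def hill_curve(c, top, bottom, ec50, hill):
    """Four-parameter logistic in its decreasing-viability orientation."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


def gen_dose_response(cfg: SimConfig, params_list: Sequence[dict] | None = None):
    """Plate-style viability table for one curve per parameter set.

    Signal = 4PL(c) + Normal(0, noise_sd * top); DMSO wells at top +/- the
    same noise.  Concentrations are written in micromolar with the unit
    declared in the table.  EC50 outside the tested range is flagged in the
    truth table rather than rejected.
    """
    cfg.validate()
    rng = _stream(cfg.seed, "dose_response")
    if params_list is None:
        params_list = [cfg.dr_params]
    conc = np.asarray(cfg.concentrations, dtype=float)

    rows = []
    truth = TruthTable()
    for ci, p in enumerate(params_list, start=1):
        if p.get("hill", 1.0) == 0:
            raise ValueError("hill = 0 is a degenerate dose-response curve")
        sid = f"C{ci:04d}"
        top, bottom, ec50, hill = p["top"], p["bottom"], p["ec50"], p["hill"]
        mu = hill_curve(conc, top, bottom, ec50, hill)
        for rep in range(1, cfg.n_replicates + 1):
            noise = rng.normal(0.0, cfg.noise_sd * top, size=conc.size)
            for c, s in zip(conc, mu + noise):
                rows.append((sid, "drug1", c * 1e6, "uM", rep, float(s), False))
        for w in range(cfg.n_dmso_wells):
            s = top + rng.normal(0.0, cfg.noise_sd * top)
            rows.append((sid, "drug1", 0.0, "uM", w + 1, float(s), True))
        truth.curves[sid] = {
            "ec50": ec50, "hill": hill, "top": top, "bottom": bottom,
            "ec50_in_range": bool(conc[0] <= ec50 <= conc[-1]),
        }
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "drug", "concentration", "unit",
                 "replicate", "signal", "is_dmso"],
    )
    return table, truth


# ---------------------------------------------------------------------------
# genotyping arm


def gen_amplicon_counts(cfg: SimConfig):
    """Amplicon ref/alt read counts: alt ~ Binomial(depth, vaf_true)."""
    cfg.validate()
    rng = _stream(cfg.seed, "amplicon")
    rows = []
    truth = TruthTable()
    for i, vaf in enumerate(cfg.vaf_true, start=1):
        sid = f"clone_{i:02d}"
        alt = int(rng.binomial(cfg.amplicon_depth, vaf))
        rows.append((sid, cfg.amplicon_depth - alt, alt))
        truth.samples[sid] = {"vaf": float(vaf)}
    table = pd.DataFrame(rows, columns=["sample_id", "ref_reads", "alt_reads"])
    return table, truth
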