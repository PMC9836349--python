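"""Synthetic genomes, occupancy tracks, site tracks, and assay time series.

The genome generator plants the three occupancy signatures of Pol II
attenuation with known ground truth, so the screen can be tested end to end
without external datasets:

1. a 5′ Pol II peak with depleted signal over the ORF body,
2. a promoter-proximal cluster of polyadenylation (pA) sites,
3. an upstream peak of the Hrp1 RNA-binding factor.

Three gene classes are emitted. *Hybrid* attenuators carry all three
signatures with low Nrd1/Nab3; *NNS* attenuators carry the 5′ Pol II peak
with high Nrd1/Nab3 (one of them, always named ``NRD1LIKE``, anchors the
reference normalization); *non-attenuated* genes have flat ORF Pol II with
pA/Hrp1 concentrated at the 3′ end. Peaks are rectangular plateaus over the
promoter-proximal window so every planted peak height — and hence every
downstream ratio — is analytically exact when noise is off.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .track_io import (GeneModel, SignalTrack, SiteTrack, write_annotation,
                       write_signal_track, write_sites)

FACTORS = ("pA", "Hrp1", "Nrd1", "Nab3")
CLASSES = ("hybrid_attenuated", "nns_attenuated", "non_attenuated")

REFERENCE_GENE_ID = "NRD1LIKE"


class ConfigError(ValueError):
    pass


def _default_reference_r() -> dict[str, float]:
    # Pol II-normalized enrichment (r) planted at the NNS reference gene:
    # moderate pA/Hrp1, strong Nrd1/Nab3 — the profile of an NNS attenuator.
    return {"pA": 0.5, "Hrp1": 0.5, "Nrd1": 2.0, "Nab3": 2.0}


def _default_class_enrichment() -> dict[str, dict[str, float]]:
    # Planted reference ratios (R = r / r_reference) per class and factor.
    # Hybrid attenuators are 3x-enriched for pA/Hrp1 and 0.3x for Nrd1/Nab3;
    # non-attenuated genes are 0.3x across the board at the promoter.
    return {
        "hybrid_attenuated": {"pA": 3.0, "Hrp1": 3.0, "Nrd1": 0.3, "Nab3": 0.3},
        "nns_attenuated": {"pA": 1.0, "Hrp1": 1.0, "Nrd1": 1.0, "Nab3": 1.0},
        "non_attenuated": {"pA": 0.3, "Hrp1": 0.3, "Nrd1": 0.3, "Nab3": 0.3},
    }


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic attenuator screen."""

    n_genes: int = 50
    fraction_hybrid_attenuated: float = 0.2
    fraction_nns_attenuated: float = 0.1
    gene_length_range: tuple[int, int] = (900, 2400)
    intergenic_gap_range: tuple[int, int] = (300, 800)
    tss_offset_range: tuple[int, int] = (30, 80)
    polII_body_level: float = 10.0
    polII_5prime_fold: float = 4.0
    promoter_upstream: int = 100
    promoter_downstream: int = 300
    reference_r: dict[str, float] = field(default_factory=_default_reference_r)
    class_enrichment: dict[str, dict[str, float]] = field(
        default_factory=_default_class_enrichment)
    pA_cluster_sites: int = 3
    pA_cluster_span: int = 30
    tss_count: float = 50.0
    noise_model: str = "none"  # none | poisson | lognormal
    noise_cv: float = 0.2
    noise_bin_bp: int = 10
    rng_seed: int = 0
    chrom: str = "chrS"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        fh, fn = self.fraction_hybrid_attenuated, self.fraction_nns_attenuated
        if not (0 <= fh <= 1 and 0 <= fn <= 1 and fh + fn <= 1):
            raise ConfigError("class fractions must lie in [0,1] and sum to <= 1")
        if self.polII_body_level <= 0 or self.polII_5prime_fold <= 0:
            raise ConfigError("Pol II levels and folds must be positive")
        for lo, hi in (self.gene_length_range, self.intergenic_gap_range,
                       self.tss_offset_range):
            if lo <= 0 or hi < lo:
                raise ConfigError("ranges must be positive with lo <= hi")
        if self.noise_model not in ("none", "poisson", "lognormal"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.gene_length_range[0] <= self.promoter_downstream:
            raise ConfigError("genes must be longer than the downstream window extent")
        for cls in CLASSES:
            if cls not in self.class_enrichment:
                raise ConfigError(f"class_enrichment missing class {cls!r}")
            for f in FACTORS:
                if self.class_enrichment[cls].get(f, 0) <= 0:
                    raise ConfigError(f"planted enrichment for {cls}/{f} must be > 0")
        for f in FACTORS:
            if self.reference_r.get(f, 0) <= 0:
                raise ConfigError(f"reference r for {f} must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated genome: class labels and planted ratios."""

    labels: dict[str, str]
    planted_R: dict[str, dict[str, float]]
    reference_gene_id: str = REFERENCE_GENE_ID

    def genes_of_class(self, label: str) -> list[str]:
        return [g for g, lbl in self.labels.items() if lbl == label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, lbl in self.labels.items():
            row = {"gene_id": gid, "class": lbl}
            row.update({f"planted_R_{f}": self.planted_R[gid][f] for f in FACTORS})
            rows.append(row)
        return pd.DataFrame(rows)


class SimulatedGenome(NamedTuple):
    genes: list[GeneModel]
    tracks: dict[str, SignalTrack]
    sites: dict[str, SiteTrack]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Genome generator
# ---------------------------------------------------------------------------

def _class_counts(config: SimulationConfig) -> dict[str, int]:
    n = config.n_genes
    n_hybrid = int(n * config.fraction_hybrid_attenuated + 0.5)
    n_nns = int(n * config.fraction_nns_attenuated + 0.5)
    n_nns = max(n_nns, 1)  # the reference gene must exist
    if n_hybrid + n_nns > n:
        n_hybrid = n - n_nns
    return {
        "hybrid_attenuated": n_hybrid,
        "nns_attenuated": n_nns,
        "non_attenuated": n - n_hybrid - n_nns,
    }


def simulate_genome(config: Optional[SimulationConfig] = None) -> SimulatedGenome:
    """Generate a genome with planted attenuation signatures.

    Returns annotation, occupancy tracks (PolII, Hrp1, Nrd1, Nab3), site
    tracks (pA, TSS) and the ground truth. A fixed ``rng_seed`` makes the
    output bit-identical across runs.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    counts = _class_counts(config)
    labels = np.array(
        sum(([cls] * counts[cls] for cls in CLASSES), []), dtype=object)
    rng.shuffle(labels)

    up, down = config.promoter_upstream, config.promoter_downstream
    body = config.polII_body_level
    peak = body * config.polII_5prime_fold

    genes: list[GeneModel] = []
    polII_runs: list[tuple[str, int, int, float]] = []
    factor_runs: dict[str, list[tuple[str, int, int, float]]] = {
        f: [] for f in FACTORS if f != "pA"}
    pa_sites: list[tuple[str, int, str, float]] = []
    tss_sites: list[tuple[str, int, str, float]] = []
    truth_labels: dict[str, str] = {}
    planted: dict[str, dict[str, float]] = {}

    nns_seen = 0
    cursor = 200
    for i in range(config.n_genes):
        label = str(labels[i])
        strand = "+" if i % 2 == 0 else "-"
        gap = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
        L = int(rng.integers(*config.gene_length_range, endpoint=True))
        off = int(rng.integers(*config.tss_offset_range, endpoint=True))

        if label == "nns_attenuated":
            nns_seen += 1
            gene_id = REFERENCE_GENE_ID if nns_seen == 1 else f"GENE{i:04d}"
        else:
            gene_id = f"GENE{i:04d}"

        if strand == "+":
            tss = cursor + gap
            atg = tss + off
            orf_start, orf_end = atg, atg + L
            wstart, wend = tss - up, tss + down
            cursor = orf_end
        else:
            orf_start = cursor + gap
            orf_end = orf_start + L
            atg = orf_end - 1
            tss = atg + off
            wstart, wend = tss - down, tss + up
            cursor = tss + up + 50
        genes.append(GeneModel(gene_id, config.chrom, strand,
                               orf_start, orf_end, tss_pos=tss))

        planted_R = {f: config.class_enrichment[label][f] for f in FACTORS}
        truth_labels[gene_id] = label
        planted[gene_id] = planted_R

        attenuated = label != "non_attenuated"
        polII_window_peak = peak if attenuated else body

        # --- Pol II ---------------------------------------------------------
        if attenuated:
            polII_runs.append((config.chrom, wstart, wend, peak))
            if strand == "+":
                polII_runs.append((config.chrom, wend, orf_end, body))
            else:
                polII_runs.append((config.chrom, orf_start, wstart, body))
        else:
            # flat occupancy across the transcribed unit (TSS to ORF end)
            if strand == "+":
                polII_runs.append((config.chrom, tss, orf_end, body))
            else:
                polII_runs.append((config.chrom, orf_start, tss + 1, body))

        # --- RNA-binding factors ---------------------------------------------
        for f in ("Hrp1", "Nrd1", "Nab3"):
            height = planted_R[f] * config.reference_r[f] * polII_window_peak
            factor_runs[f].append((config.chrom, wstart, wend, height))
        if not attenuated:
            # 3' Hrp1 peak of a conventionally terminated gene
            h3 = 2.0 * body
            if strand == "+":
                factor_runs["Hrp1"].append(
                    (config.chrom, orf_end - 150, orf_end, h3))
            else:
                factor_runs["Hrp1"].append(
                    (config.chrom, orf_start, orf_start + 150, h3))

        # --- pA and TSS sites -------------------------------------------------
        max_count = planted_R["pA"] * config.reference_r["pA"] * polII_window_peak
        n_sites = config.pA_cluster_sites
        span = config.pA_cluster_span
        # orientation offsets inside the promoter window, just 3' of the ATG
        main_idx = up + off + 40
        fractions = np.linspace(1.0, 0.3, n_sites) if n_sites > 1 else np.array([1.0])
        for k in range(n_sites):
            idx = main_idx - (0 if n_sites == 1 else round(k * span / (n_sites - 1)))
            pos = wstart + idx if strand == "+" else wend - 1 - idx
            pa_sites.append((config.chrom, pos, strand, max_count * fractions[k]))
        if not attenuated:
            # dominant 3'-end cluster, as at conventionally terminated genes
            for k in range(n_sites):
                if strand == "+":
                    pos = orf_end - 20 - 10 * k
                else:
                    pos = orf_start + 20 + 10 * k
                pa_sites.append((config.chrom, pos, strand, 3.0 * body * fractions[k]))
        tss_sites.append((config.chrom, tss, strand, config.tss_count))

    # --- noise ---------------------------------------------------------------
    if config.noise_model == "lognormal" and config.noise_cv > 0:
        polII_runs = _lognormal_runs(polII_runs, config, rng)
        factor_runs = {f: _lognormal_runs(r, config, rng)
                       for f, r in factor_runs.items()}
    if config.noise_model in ("poisson", "lognormal"):
        pa_sites = [(c, p, s, max(1.0, float(rng.poisson(cnt))))
                    for c, p, s, cnt in pa_sites]
        tss_sites = [(c, p, s, max(1.0, float(rng.poisson(cnt))))
                     for c, p, s, cnt in tss_sites]

    tracks = {"PolII": SignalTrack.from_intervals(polII_runs)}
    for f, runs in factor_runs.items():
        tracks[f] = SignalTrack.from_intervals(runs)
    sites = {"pA": SiteTrack.from_sites(pa_sites),
             "TSS": SiteTrack.from_sites(tss_sites)}
    truth = SyntheticTruth(labels=truth_labels, planted_R=planted)
    return SimulatedGenome(genes, tracks, sites, truth)


def _lognormal_runs(runs, config: SimulationConfig, rng: np.random.Generator):
    """Split runs into fixed-width bins and jitter each with mean-1 lognormal
    noise. Binning emulates per-position coverage noise; a window's peak is
    then a maximum over many mildly noisy bins rather than one draw."""
    sigma = float(np.sqrt(np.log1p(config.noise_cv ** 2)))
    out = []
    w = config.noise_bin_bp
    for chrom, start, end, value in runs:
        edges = list(range(start, end, w)) + [end]
        for a, b in zip(edges[:-1], edges[1:]):
            mult = float(np.exp(rng.normal(0.0, sigma) - sigma ** 2 / 2))
            out.append((chrom, a, b, value * mult))
    return out


def write_genome(sim: SimulatedGenome, outdir, config: SimulationConfig) -> dict[str, str]:
    """Write a simulated genome in the exact formats the readers accept.

    Emits annotation.tsv, one bedGraph per occupancy track, one BED per site
    track, truth.tsv and a config echo; returns the path map.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    paths["annotation"] = os.path.join(outdir, "annotation.tsv")
    write_annotation(sim.genes, paths["annotation"])
    for name, track in sim.tracks.items():
        paths[name] = os.path.join(outdir, f"{name.lower()}.bedgraph")
        write_signal_track(track, paths[name])
    for name, st in sim.sites.items():
        paths[name] = os.path.join(outdir, f"{name.lower()}.bed")
        write_sites(st, paths[name], name_prefix=name.lower())
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    sim.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = os.path.join(outdir, "config.json")
    with open(paths["config"], "w") as fh:
        fh.write(config.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# Attenuator panel fixture
# ---------------------------------------------------------------------------

#: The ten cloned attenuator windows, as ATG-relative coordinates (+1 ATG).
ATTENUATOR_PANEL: tuple[tuple[str, int, int], ...] = (
    ("HDA2", -283, -1),
    ("MNR2", -225, 116),
    ("PTI1", -201, 195),
    ("RAD3", -139, 175),
    ("RPN4", -264, 98),
    ("SNG1", -262, 115),
    ("SVF1", -234, 117),
    ("TEC1", -112, 297),
    ("UBC1", -126, 173),
    ("VTS1", -187, 82),
)


def fixture_attenuator_panel() -> pd.DataFrame:
    """The ten experimentally cloned attenuator windows relative to the +1 ATG."""
    return pd.DataFrame(ATTENUATOR_PANEL, columns=["gene_id", "rel_start", "rel_end"])


def write_attenuator_panel(path) -> None:
    fixture_attenuator_panel().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assay simulators
# ---------------------------------------------------------------------------

def simulate_kinetic_assay(true_slope: float, lag_min: float = 0.0,
                           saturation_od: Optional[float] = None,
                           duration: int = 60, interval: int = 1,
                           noise_sd: float = 0.0, seed: int = 0,
                           od600: float = 0.3, volume_ml: float = 0.1):
    """Simulate a kinetic β-galactosidase reporter read (OD420 vs minutes).

    The series is flat during ``lag_min``, rises linearly at ``true_slope``
    (OD420/min), plateaus at ``saturation_od`` if given, and carries additive
    Gaussian noise of SD ``noise_sd``.
    """
    from .reporter_assays import KineticSeries

    if true_slope <= 0:
        raise ConfigError("true_slope must be positive")
    time = np.arange(0.0, duration + 1e-9, interval)
    if len(time) < 3:
        raise ConfigError("duration/interval must yield at least 3 points")
    od = np.where(time < lag_min, 0.0, true_slope * (time - lag_min))
    if saturation_od is not None:
        od = np.minimum(od, saturation_od)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return KineticSeries(time=time, od420=od, od600=od600, volume_ml=volume_ml)


def simulate_growth_curve(od0: float, doubling_time_min: float,
                          duration: int = 360, interval: int = 60,
                          cv: float = 0.0, seed: int = 0):
    """Simulate an exponential OD600 growth curve with multiplicative
    lognormal noise: OD(t) = od0 · 2^(t/doubling_time) · ε(cv)."""
    if od0 <= 0 or doubling_time_min <= 0:
        raise ConfigError("od0 and doubling_time_min must be positive")
    time = np.arange(0.0, duration + 1e-9, interval)
    od = od0 * np.power(2.0, time / doubling_time_min)
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv ** 2)))
        rng = np.random.default_rng(seed)
        od = od * np.exp(rng.normal(0.0, sigma, size=od.shape) - sigma ** 2 / 2)
    return time, od
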