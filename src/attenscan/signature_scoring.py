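"""Promoter-proximal enrichment scoring and attenuator-candidate selection.

The screen quantifies, for each gene, the peak height of polyadenylation (pA)
sites and of the RNA-binding factors Hrp1, Nrd1 and Nab3 in a promoter-proximal
window, normalizes each peak to the local Pol II peak (r = peak / Pol II peak,
controlling for transcription rate), then normalizes each r to the same
quantity at a model NNS-dependent attenuator gene (reference ratio
R = r / r_ref). R values are binned into three categories — low (0–0.67),
intermediate (0.67–1.5) and high (>1.5) — and candidate attenuators are genes
with high pA and Hrp1 enrichment but low Nrd1/Nab3 relative to the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .track_io import GeneModel, GenomicWindow, SignalTrack, SiteTrack

logger = logging.getLogger("attenscan")

#: zero-division guard for Pol II normalization, in signal units
DEFAULT_EPSILON = 1e-9

#: category bin edges on the reference ratio R
DEFAULT_BIN_EDGES = (0.67, 1.5)

#: promoter-proximal window extent around the 5' anchor (TSS, else ATG)
DEFAULT_WINDOW = (100, 300)  # (upstream_bp, downstream_bp)

CATEGORIES = ("low", "intermediate", "high")

Track = Union[SignalTrack, SiteTrack]


class ScoringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Windows and peaks
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneModel, upstream_bp: int = DEFAULT_WINDOW[0],
                    downstream_bp: int = DEFAULT_WINDOW[1]) -> GenomicWindow:
    """Promoter-proximal window around the gene's 5′ anchor.

    Anchored at the TSS when annotated, else at the +1 ATG; extends
    ``upstream_bp`` 5′ and ``downstream_bp`` 3′ in gene orientation and is
    clipped at position 0.
    """
    if upstream_bp < 0 or downstream_bp < 0 or (upstream_bp == 0 and downstream_bp == 0):
        raise ScoringError("window extents must be >= 0 and not both 0")
    anchor = gene.anchor
    if gene.strand == "+":
        start, end = anchor - upstream_bp, anchor + downstream_bp
    else:
        # mirror image: upstream lies at higher coordinates on the − strand
        start, end = anchor - downstream_bp, anchor + upstream_bp
    start = max(start, 0)
    return GenomicWindow(gene.chrom, start, end, gene.strand)


def peak_height(track: Track, window: GenomicWindow, stat: str = "max") -> float:
    """Peak height of a signal or site track in a window.

    For occupancy tracks: the maximum per-base value (``stat="sum"`` gives the
    area instead). For site tracks: the maximum single-site count among sites
    in the window on the window's strand (``stat="sum"`` sums the counts);
    0 when the window holds no signal.
    """
    if stat not in ("max", "sum"):
        raise ScoringError(f"unknown peak statistic {stat!r}")
    if isinstance(track, SiteTrack):
        _, counts = track.in_window(window)
        if len(counts) == 0:
            return 0.0
        return float(counts.max() if stat == "max" else counts.sum())
    values = track.window_values(window)
    return float(values.max() if stat == "max" else values.sum())


def normalized_enrichment(factor_peak: float, polII_peak: float,
                          epsilon: float = DEFAULT_EPSILON) -> float:
    """Factor peak normalized to the local Pol II peak: r = peak / max(Pol II, ε).

    The Pol II denominator controls for per-gene transcription rate; ε guards
    empty windows (a warning is logged when it kicks in).
    """
    if factor_peak < 0 or polII_peak < 0:
        raise ScoringError("peak heights must be nonnegative")
    if epsilon <= 0:
        raise ScoringError("epsilon must be positive")
    if polII_peak < epsilon:
        logger.warning(
            "Pol II peak %g below epsilon %g; ratio is epsilon-guarded",
            polII_peak, epsilon,
        )
    return factor_peak / max(polII_peak, epsilon)


def reference_normalize(r_by_gene: Mapping[str, float], reference_gene_id: str,
                        factor: str = "") -> dict[str, float]:
    """Divide each gene's r by the reference gene's r for the same factor.

    The reference gene's own R is exactly 1. A missing reference or a
    reference with r = 0 is a hard error: the screen has no anchor then.
    """
    if reference_gene_id not in r_by_gene:
        raise ScoringError(
            f"reference gene {reference_gene_id!r} absent from records"
            + (f" for factor {factor}" if factor else "")
        )
    r_ref = r_by_gene[reference_gene_id]
    if r_ref <= 0:
        raise ScoringError(
            f"reference gene {reference_gene_id!r} has zero enrichment"
            + (f" for factor {factor}" if factor else "")
        )
    out = {g: r / r_ref for g, r in r_by_gene.items()}
    out[reference_gene_id] = 1.0
    return out


def categorize(R: float, low_edge: float = DEFAULT_BIN_EDGES[0],
               high_edge: float = DEFAULT_BIN_EDGES[1]) -> str:
    """Bin a reference ratio: R ≤ low_edge → low; ≤ high_edge → intermediate;
    above → high. Only "> high_edge" is strict, matching the published bins."""
    if R < 0:
        raise ScoringError(f"reference ratio must be nonnegative, got {R}")
    if not 0 < low_edge < high_edge:
        raise ScoringError("bin edges must satisfy 0 < low < high")
    if R <= low_edge:
        return "low"
    if R <= high_edge:
        return "intermediate"
    return "high"


# ---------------------------------------------------------------------------
# Heatmap assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentRecord:
    """One gene × factor cell of the screen."""

    gene_id: str
    factor: str
    raw_peak: float
    polII_peak: float
    r: float
    R: float
    category: str


@dataclass
class HeatmapTable:
    """Genes × factors grid of enrichment records.

    ``records`` is a long-format DataFrame (one row per gene × factor) with
    columns gene_id, factor, raw_peak, polII_peak, r, R, category.
    """

    records: pd.DataFrame
    reference_gene_id: str
    bin_edges: tuple[float, float] = DEFAULT_BIN_EDGES
    factors: tuple[str, ...] = ()
    gene_order: tuple[str, ...] = ()

    def pivot(self, value: str = "R") -> pd.DataFrame:
        """Genes × factors matrix of one quantity (default the reference ratio)."""
        wide = self.records.pivot(index="gene_id", columns="factor", values=value)
        return wide.reindex(index=list(self.gene_order), columns=list(self.factors))

    def cell(self, gene_id: str, factor: str) -> EnrichmentRecord:
        row = self.records[(self.records.gene_id == gene_id)
                           & (self.records.factor == factor)]
        if row.empty:
            raise KeyError((gene_id, factor))
        r = row.iloc[0]
        return EnrichmentRecord(r.gene_id, r.factor, r.raw_peak, r.polII_peak,
                                r.r, r.R, r.category)

    def to_tsv(self, path, candidates: Optional[Sequence[str]] = None) -> None:
        out = self.records.copy()
        if candidates is not None:
            flagged = set(candidates)
            out["candidate"] = out.gene_id.isin(flagged).astype(int)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_heatmap(genes: Sequence[GeneModel],
                  tracks: Mapping[str, SignalTrack],
                  sites: Optional[Mapping[str, SiteTrack]] = None,
                  window_params: tuple[int, int] = DEFAULT_WINDOW,
                  reference_gene_id: str = "NRD1",
                  bin_edges: tuple[float, float] = DEFAULT_BIN_EDGES,
                  epsilon: float = DEFAULT_EPSILON,
                  peak_stat: str = "max") -> HeatmapTable:
    """Score every gene × factor cell of the attenuator screen.

    ``tracks`` must contain a ``"PolII"`` occupancy track plus the factor
    tracks; ``sites`` holds stranded site tracks (typically ``"pA"``). For
    each gene, each factor's promoter-proximal peak is normalized to the
    Pol II peak in the same window and then to the reference attenuator gene.
    The Pol II column itself is carried through the same chain and is 1
    everywhere by construction.
    """
    sites = sites or {}
    if "PolII" not in tracks:
        raise ScoringError("a 'PolII' track is mandatory")
    factor_tracks: dict[str, Track] = {
        name: trk for name, trk in tracks.items()
    }
    for name, st in sites.items():
        if name in factor_tracks:
            raise ScoringError(f"duplicate factor name {name!r} in tracks and sites")
        factor_tracks[name] = st
    if len(factor_tracks) < 2:
        raise ScoringError("need at least one factor or site track besides Pol II")
    gene_ids = [g.gene_id for g in genes]
    if reference_gene_id not in gene_ids:
        raise ScoringError(f"reference gene {reference_gene_id!r} not in annotation")
    if len(set(gene_ids)) != len(gene_ids):
        raise ScoringError("duplicate gene ids in annotation")

    # canonical column order: sites first (pA), then factors, Pol II last
    site_names = sorted(sites)
    signal_names = sorted(n for n in tracks if n != "PolII")
    factor_order = tuple(site_names + signal_names + ["PolII"])

    windows = {g.gene_id: promoter_window(g, *window_params) for g in genes}
    polII_peaks = {
        gid: peak_height(tracks["PolII"], win, stat=peak_stat)
        for gid, win in windows.items()
    }

    rows = []
    for factor in factor_order:
        trk = factor_tracks[factor]
        raw = {gid: peak_height(trk, windows[gid], stat=peak_stat)
               for gid in gene_ids}
        r = {gid: normalized_enrichment(raw[gid], polII_peaks[gid], epsilon)
             for gid in gene_ids}
        R = reference_normalize(r, reference_gene_id, factor=factor)
        for gid in gene_ids:
            rows.append({
                "gene_id": gid, "factor": factor,
                "raw_peak": raw[gid], "polII_peak": polII_peaks[gid],
                "r": r[gid], "R": R[gid],
                "category": categorize(R[gid], *bin_edges),
            })
    records = pd.DataFrame(rows)
    return HeatmapTable(records=records, reference_gene_id=reference_gene_id,
                        bin_edges=tuple(bin_edges), factors=factor_order,
                        gene_order=tuple(gene_ids))


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateCriteria:
    """Selection rule for putative attenuators.

    A gene is a candidate when R exceeds ``enrich_threshold`` (strictly) for
    every enrichment factor AND, when depletion factors are given, R is at or
    below ``deplete_threshold`` for every one of them (``deplete_mode="all"``)
    or for at least one (``"any"``).
    """

    enrich_factors: tuple[str, ...] = ("Hrp1", "pA")
    enrich_threshold: float = 1.5
    deplete_factors: tuple[str, ...] = ("Nrd1", "Nab3")
    deplete_threshold: float = 0.67
    deplete_mode: str = "all"

    def __post_init__(self):
        if self.enrich_threshold <= 0 or self.deplete_threshold <= 0:
            raise ScoringError("criteria thresholds must be positive")
        if set(self.enrich_factors) & set(self.deplete_factors):
            raise ScoringError("enrich and deplete factor sets must be disjoint")
        if self.deplete_mode not in ("all", "any"):
            raise ScoringError("deplete_mode must be 'all' or 'any'")


def select_candidates(table: HeatmapTable,
                      criteria: CandidateCriteria = CandidateCriteria()) -> list[str]:
    """Genes passing the enrichment/depletion rule, ranked by strength.

    Output is sorted by descending minimum enrichment-factor R (the weakest
    qualifying enrichment), ties broken by gene id.
    """
    needed = set(criteria.enrich_factors) | set(criteria.deplete_factors)
    missing = needed - set(table.factors)
    if missing:
        raise ScoringError(f"criteria name factors absent from table: {sorted(missing)}")
    R = table.pivot("R")
    selected: list[tuple[float, str]] = []
    for gid in table.gene_order:
        enrich_R = [R.at[gid, f] for f in criteria.enrich_factors]
        if not all(v > criteria.enrich_threshold for v in enrich_R):
            continue
        if criteria.deplete_factors:
            deplete_ok = [R.at[gid, f] <= criteria.deplete_threshold
                          for f in criteria.deplete_factors]
            ok = all(deplete_ok) if criteria.deplete_mode == "all" else any(deplete_ok)
            if not ok:
                continue
        selected.append((min(enrich_R), gid))
    selected.sort(key=lambda t: (-t[0], t[1]))
    return [gid for _, gid in selected]


def pol2_travel_ratio(polII: SignalTrack, gene: GeneModel,
                      window_params: tuple[int, int] = DEFAULT_WINDOW,
                      epsilon: float = DEFAULT_EPSILON) -> float:
    """Mean Pol II in the promoter-proximal window over mean in the ORF body.

    The body is the ORF minus its overlap with the promoter-proximal window.
    High values mean Pol II accumulates at the 5′ end and thins out over the
    body — the occupancy signature of attenuation.
    """
    win = promoter_window(gene, *window_params)
    if gene.strand == "+":
        body_start, body_end = max(gene.orf_start, win.end), gene.orf_end
    else:
        body_start, body_end = gene.orf_start, min(gene.orf_end, win.start)
    if body_start >= body_end:
        raise ScoringError(
            f"gene {gene.gene_id}: ORF is fully inside the promoter-proximal window"
        )
    body = GenomicWindow(gene.chrom, body_start, body_end, gene.strand)
    win_mean = float(polII.window_values(win).mean())
    body_mean = float(polII.window_values(body).mean())
    if body_mean < epsilon:
        logger.warning("gene %s: ORF-body Pol II mean below epsilon", gene.gene_id)
    return win_mean / max(body_mean, epsilon)
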