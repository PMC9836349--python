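"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the package's run-length representation and prefix
sums: tracks are expanded into per-base hash maps, peaks are found by
scanning every base, and slope windows are re-fit with numpy.polyfit.
"""

from __future__ import annotations

import numpy as np


def track_to_basemap(track) -> dict[str, dict[int, float]]:
    """Expand a SignalTrack into per-chromosome {position: value} dicts."""
    out: dict[str, dict[int, float]] = {}
    for chrom, start, end, value in track.iter_runs():
        chrom_map = out.setdefault(chrom, {})
        for pos in range(start, end):
            chrom_map[pos] = value
    return out


def naive_signal_peak(basemap, chrom, start, end, stat="max") -> float:
    values = [basemap.get(chrom, {}).get(pos, 0.0) for pos in range(start, end)]
    return float(max(values) if stat == "max" else sum(values))


def naive_signal_mean(basemap, chrom, start, end) -> float:
    values = [basemap.get(chrom, {}).get(pos, 0.0) for pos in range(start, end)]
    return float(np.mean(values))


def naive_site_peak(site_track, chrom, start, end, strand, stat="max") -> float:
    counts = [c for c2, p, s, c in site_track.iter_sites()
              if c2 == chrom and s == strand and start <= p < end]
    if not counts:
        return 0.0
    return float(max(counts) if stat == "max" else sum(counts))


def naive_categorize(R, low=0.67, high=1.5) -> str:
    if R <= low:
        return "low"
    elif R <= high:
        return "intermediate"
    return "high"


def naive_heatmap(genes, tracks, pa_sites, reference_gene_id,
                  upstream=100, downstream=300, epsilon=1e-9):
    """Recompute every heatmap cell by per-base scanning.

    Returns {gene_id: {factor: (r, R, category)}} for the factors
    pA, Hrp1, Nrd1, Nab3, PolII.
    """
    basemaps = {name: track_to_basemap(trk) for name, trk in tracks.items()}
    windows = {}
    for g in genes:
        anchor = g.tss_pos if g.tss_pos is not None else (
            g.orf_start if g.strand == "+" else g.orf_end - 1)
        if g.strand == "+":
            start, end = anchor - upstream, anchor + downstream
        else:
            start, end = anchor - downstream, anchor + upstream
        windows[g.gene_id] = (g.chrom, max(start, 0), end, g.strand)

    polII_peak = {}
    for g in genes:
        chrom, start, end, _ = windows[g.gene_id]
        polII_peak[g.gene_id] = naive_signal_peak(basemaps["PolII"], chrom, start, end)

    factors = ["pA"] + sorted(n for n in tracks if n != "PolII") + ["PolII"]
    r_values: dict[str, dict[str, float]] = {f: {} for f in factors}
    for g in genes:
        chrom, start, end, strand = windows[g.gene_id]
        for f in factors:
            if f == "pA":
                raw = naive_site_peak(pa_sites, chrom, start, end, strand)
            else:
                raw = naive_signal_peak(basemaps[f], chrom, start, end)
            r_values[f][g.gene_id] = raw / max(polII_peak[g.gene_id], epsilon)

    out: dict[str, dict[str, tuple]] = {}
    for f in factors:
        r_ref = r_values[f][reference_gene_id]
        for g in genes:
            R = 1.0 if g.gene_id == reference_gene_id else r_values[f][g.gene_id] / r_ref
            out.setdefault(g.gene_id, {})[f] = (
                r_values[f][g.gene_id], R, naive_categorize(R))
    return out


def naive_candidates(cell_map, enrich=("Hrp1", "pA"), enrich_thr=1.5,
                     deplete=("Nrd1", "Nab3"), deplete_thr=0.67):
    picked = []
    for gid, cells in cell_map.items():
        if all(cells[f][1] > enrich_thr for f in enrich) and \
                all(cells[f][1] <= deplete_thr for f in deplete):
            picked.append((min(cells[f][1] for f in enrich), gid))
    picked.sort(key=lambda t: (-t[0], t[1]))
    return [gid for _, gid in picked]


def exhaustive_slope_window(time, od420, min_points=10, r2_floor=0.995):
    """Enumerate every contiguous window with numpy.polyfit and apply the
    selection rule. Returns (slope, (start, end), r2, low_confidence)."""
    t = np.asarray(time, float)
    y = np.asarray(od420, float)
    n = len(t)
    qualifying = []
    fallback = []
    for i in range(n):
        for j in range(i + min_points, n + 1):
            coeffs = np.polyfit(t[i:j], y[i:j], 1)
            fit = np.polyval(coeffs, t[i:j])
            ss_res = float(((y[i:j] - fit) ** 2).sum())
            ss_tot = float(((y[i:j] - y[i:j].mean()) ** 2).sum())
            r2 = 1.0 if ss_tot <= 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
            slope = float(coeffs[0])
            if j - i == min_points:
                fallback.append((r2, -i, slope))
            if r2 >= r2_floor:
                qualifying.append((j - i, r2, -i, slope))
    if qualifying:
        length, r2, neg_i, slope = max(qualifying)
        return slope, (-neg_i, -neg_i + length), r2, False
    r2, neg_i, slope = max(fallback)
    return slope, (-neg_i, -neg_i + min_points), r2, True


def mirror_genome(sim, mirror_point):
    """Reflect a simulated genome through ``mirror_point`` (strand flip).

    Intervals [s, e) map to [M - e, M - s); a site at base b maps to base
    M - 1 - b; a gene's TSS anchor maps to M - tss so that oriented
    promoter-proximal windows map onto each other's base sets exactly.
    """
    from attenscan.synthetic_data import SimulatedGenome
    from attenscan.track_io import GeneModel, SignalTrack, SiteTrack

    M = mirror_point
    flip = {"+": "-", "-": "+"}
    genes = [
        GeneModel(g.gene_id, g.chrom, flip[g.strand],
                  M - g.orf_end, M - g.orf_start,
                  tss_pos=None if g.tss_pos is None else M - g.tss_pos)
        for g in sim.genes
    ]
    tracks = {
        name: SignalTrack.from_intervals(
            [(c, M - e, M - s, v) for c, s, e, v in trk.iter_runs()])
        for name, trk in sim.tracks.items()
    }
    sites = {
        name: SiteTrack.from_sites(
            [(c, M - 1 - p, flip[s], cnt) for c, p, s, cnt in st.iter_sites()])
        for name, st in sim.sites.items()
    }
    return SimulatedGenome(genes, tracks, sites, sim.truth)
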