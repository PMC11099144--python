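"""Synthetic two-program time courses with planted activation waves.

Generates expression fixtures that mimic a short developmental time course:
TF genes are organized in sequential waves, each wave a Gaussian bump of
expression peaking at successive positions along the condition axis (wave
centers extend slightly beyond the sampled range so the first and last
waves look monotone, like genes still rising at the final stage).
Background (non-TF) genes co-vary with a randomly chosen wave so that
level gene sets and their enrichment are testable; a configurable fraction
of genes is non-expressed (max TPM < 1). A shift map can move selected TFs
to a different wave in one program, planting program-specific late TFs.

Generation is a pure function of the configuration, including the RNG
seed; gene-level parameters are shared between the two programs while
replicate noise uses independent per-program substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import TermCollection, write_gmt
from .expr_io import (
    ExpressionMatrix,
    SampleSheet,
    write_expression_matrix,
    write_gene_list,
    write_sample_sheet,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "tf_gene_ids",
    "make_shift_map",
    "simulate_timecourse",
    "write_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_conditions: int = 5
    replicates: int = 3
    n_waves: int = 8
    tfs_per_wave: int = 15
    n_background_genes: int = 400
    bump_width: float = 0.6
    amplitude: float = 100.0
    noise_sd_frac: float = 0.05
    shift_map: dict[str, tuple[int, int]] = field(default_factory=dict)
    frac_nonexpressed: float = 0.1
    rng_seed: int = 0
    # log-normal spread of per-gene peak amplitudes
    amp_log_sd: float = 0.2
    # Wave centers are placed at equal steps of correlation arc length so
    # that the noiseless PCC between adjacent waves is adj_r_target in
    # every gap (uniform spacing in time would make outer gaps far more
    # correlated than inner ones at 5 conditions).
    adj_r_target: float = 0.89
    # Condition-level (biological) noise, shared by a condition's
    # replicates, drawn per gene from U(gene_noise_lo, gene_noise_hi)
    # relative to the gene's own profile SD. The whole component scales
    # with noise_sd_frac (zero noise => exact PCC within a wave). The TF
    # band is kept narrow so that which adjacent-wave pairs clear the
    # cutoff is pairwise luck rather than a property of single genes —
    # otherwise noisy TFs lose all their backward edges at once and whole
    # waves smear across levels. Background genes get a wider, noisier
    # band so each co-expressed gene set stays specific to its own wave.
    gene_noise_lo: float = 0.02
    gene_noise_hi: float = 0.05
    bg_noise_lo: float = 0.48
    bg_noise_hi: float = 0.56
    # the seed TF leads its wave by this fraction of a wave gap, so it is
    # tightly co-expressed with wave 1 but cannot reach wave-2 TFs
    # directly (which would shift every level down by one)
    seed_lead: float = 1.0
    # TFs outside the activation cascade (the bulk of any real TF catalog):
    # flat baseline plus a stable random shape component, shared between
    # the two programs. They dilute the TF-TF pair pool so that the
    # empirical 95th-percentile cutoff falls inside the adjacent-wave
    # correlation tier; almost all stay unconnected (reported as unreached
    # by the BFS), and the rare one whose shape happens to mimic a wave
    # attaches identically in both programs because the shape is a gene
    # property, not noise.
    n_scatter_tfs: int = 300
    scatter_shape_sd: float = 0.35
    scatter_module_size: int = 1
    scatter_module_cos: float = 0.82
    scatter_max_curve_cos: float = 0.66
    # basal expression added to every wave profile (fraction of the gene's
    # amplitude). Without it the zero floor clips noise at off-peak
    # conditions and systematically tilts profiles toward the mid-range.
    baseline_frac: float = 0.40
    # flat constitutive genes that pin the upper-quartile normalization
    # (without them the per-sample UQ tracks the wave structure and the
    # normalization distorts every profile with a shared condition factor)
    n_housekeeping: int = 200

    def __post_init__(self) -> None:
        if min(self.n_conditions, self.replicates, self.n_waves, self.tfs_per_wave) < 1:
            raise ValueError("counts must be positive")
        if self.n_background_genes < 0 or self.n_scatter_tfs < 0 or self.n_housekeeping < 0:
            raise ValueError("gene counts must be >= 0")
        if not 0 <= self.frac_nonexpressed < 1:
            raise ValueError("frac_nonexpressed must be in [0, 1)")
        if not 0 <= self.noise_sd_frac < 1:
            raise ValueError("noise_sd_frac must be in [0, 1)")
        if self.bump_width <= 0 or self.amplitude <= 0:
            raise ValueError("bump_width and amplitude must be positive")
        known = set(tf_gene_ids(self.n_waves, self.tfs_per_wave))
        for tf, (wa, wb) in self.shift_map.items():
            if tf not in known:
                raise ValueError(f"shift_map references unknown TF {tf!r}")
            for w in (wa, wb):
                if not 1 <= w <= self.n_waves:
                    raise ValueError(f"shift_map wave {w} out of range for {tf!r}")


def tf_gene_ids(n_waves: int, tfs_per_wave: int) -> list[str]:
    """Deterministic TF gene IDs, ordered by base wave then index."""
    return [
        f"TF_W{w:02d}_{i:02d}"
        for w in range(1, n_waves + 1)
        for i in range(1, tfs_per_wave + 1)
    ]


def base_wave(tf_id: str) -> int:
    return int(tf_id.split("_")[1][1:])


def make_shift_map(
    cfg: SimulationConfig,
    frac_shifted: float = 0.1,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[int, int]]:
    """Plant window shifts: move a fraction of early TFs to the last wave
    in exactly one program, leaving their wave in the other unchanged."""
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    ids = tf_gene_ids(cfg.n_waves, cfg.tfs_per_wave)
    # the wave-1 seed TF roots the BFS in both programs and stays unshifted
    early = [
        g
        for g in ids
        if base_wave(g) <= max(1, cfg.n_waves - 3) and g != "TF_W01_01"
    ]
    n_shift = int(round(frac_shifted * len(ids)))
    chosen = rng.choice(early, size=min(n_shift, len(early)), replace=False)
    out: dict[str, tuple[int, int]] = {}
    for tf in sorted(chosen):
        w = base_wave(tf)
        if rng.random() < 0.5:
            out[tf] = (cfg.n_waves, w)  # shifted into the window in program A
        else:
            out[tf] = (w, cfg.n_waves)  # shifted into the window in program B
    return out


@dataclass(frozen=True)
class SyntheticDataset:
    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    sheet_a: SampleSheet
    sheet_b: SampleSheet
    truth: pd.DataFrame = field(repr=False)  # gene_id, wave_a, wave_b, is_tf, is_expressed
    tf_ids: tuple[str, ...]
    seed_a: str
    seed_b: str
    config: SimulationConfig

    def expressed_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["is_expressed"], "gene_id"])


def _bump(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * width**2))


def _condition_noise(
    mean: np.ndarray,
    sd: float,
    rng: np.random.Generator,
    avoid: np.ndarray | None = None,
    avoid_cos: float = 0.35,
    exact: bool = False,
) -> np.ndarray:
    """Condition-level noise with a capped realized magnitude.

    A raw Gaussian draw over so few conditions has a heavy-tailed realized
    magnitude (chi distribution). The clean tail is useful — genes that
    drew little noise knit the co-expression web together — but the noisy
    tail would leave genes with no partner above any sensible cutoff, so
    the realized population SD is capped at ``sd`` (direction kept, excess
    magnitude trimmed). The draw is centered and projected off the profile
    direction so the cap controls co-expression strength directly. Rows of
    ``avoid`` (unit vectors) are directions the noise must stay away from
    (cosine <= avoid_cos); used to keep background genes from drifting
    toward a neighboring wave's profile and swamping its gene set.
    """
    if sd <= 0:
        return np.zeros_like(mean)
    for _ in range(64):
        e = rng.normal(0.0, sd, size=mean.size)
        e = e - e.mean()
        p = mean - mean.mean()
        pn = float(p @ p)
        if pn > 0:
            e = e - (float(e @ p) / pn) * p
        nrm = float(np.linalg.norm(e))
        if nrm <= 0:
            continue
        if avoid is not None and len(avoid):
            if (avoid @ (e / nrm)).max() > avoid_cos:
                continue
        realized = float(e.std())
        if exact and realized > 0:
            return e * (sd / realized)
        if realized > sd:
            e = e * (sd / realized)
        return e
    return e  # pragma: no cover - rejection practically always succeeds


def _wave_centers(cfg: SimulationConfig) -> np.ndarray:
    """Place wave centers at equal correlation arc-length steps.

    The centered, normalized bump profile over the sampled conditions
    traces a curve on the unit sphere as its center moves. Stepping along
    that curve by ``arccos(adj_r_target)`` per wave makes the noiseless
    PCC between neighboring waves equal to ``adj_r_target`` in every gap;
    the n_waves centers are placed symmetrically around the curve's arc
    midpoint.
    """
    x = np.arange(1, cfg.n_conditions + 1, dtype=float)
    span = 4.0 * cfg.bump_width + 2.0
    grid = np.linspace(1.0 - span, cfg.n_conditions + span, 4001)
    vecs = []
    cs = []
    for c in grid:
        y = _bump(x, c, cfg.bump_width)
        y = y - y.mean()
        norm = np.linalg.norm(y)
        if norm > 1e-9:
            vecs.append(y / norm)
            cs.append(c)
    vecs_arr = np.array(vecs)
    cs_arr = np.array(cs)
    steps = np.degrees(
        np.arccos(np.clip(np.sum(vecs_arr[:-1] * vecs_arr[1:], axis=1), -1.0, 1.0))
    )
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    theta = np.degrees(np.arccos(cfg.adj_r_target))
    # position 0 is the seed's own center, leading wave 1 by seed_lead * theta
    offsets = np.concatenate([[-cfg.seed_lead * theta], np.arange(cfg.n_waves) * theta])
    span = offsets[-1] - offsets[0]
    if span > arc[-1]:
        raise ValueError(
            f"cannot fit {cfg.n_waves} waves at adjacent PCC {cfg.adj_r_target} "
            f"with {cfg.n_conditions} conditions and bump width {cfg.bump_width}"
        )
    start = (arc[-1] - span) / 2.0 - offsets[0]
    return np.interp(start + offsets, arc, cs_arr)


def _draw_far_directions(
    n: int,
    curve: np.ndarray,
    n_cond: int,
    rng: np.random.Generator,
    max_cos: float,
    mix_with: np.ndarray | None = None,
    mix_weight: float = 0.0,
) -> np.ndarray:
    """Centered unit vectors with cosine to every curve sample <= max_cos.

    With ``mix_with``/``mix_weight`` the accepted draw is a blend
    ``sqrt(w)*base + sqrt(1-w)*random`` (used for module members).
    """
    out = np.empty((n, n_cond))
    for i in range(n):
        while True:
            e = rng.normal(size=n_cond)
            e -= e.mean()
            nrm = np.linalg.norm(e)
            if nrm <= 1e-9:
                continue
            e /= nrm
            if mix_with is not None:
                e = np.sqrt(mix_weight) * mix_with[i] + np.sqrt(1.0 - mix_weight) * e
                e -= e.mean()
                e /= np.linalg.norm(e)
            if (curve @ e).max() <= max_cos:
                out[i] = e
                break
    return out


def _scatter_directions(
    n: int,
    centers: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Module-structured shape vectors for the non-cascade TFs.

    Non-cascade TFs come in co-regulated modules: members of a module share
    a common direction (pairwise cosine ~ scatter_module_cos), while
    module directions are random but rejected until their cosine to every
    bump profile along the wave curve is at most scatter_max_curve_cos, so
    no non-cascade TF can cross the co-expression cutoff with a cascade
    gene. The dense within-module pair band sits just below the
    adjacent-wave correlation tier and pins the empirical cutoff there.
    Returned vectors are scaled to unit population SD.
    """
    x = np.arange(1, cfg.n_conditions + 1, dtype=float)
    grid = np.linspace(centers.min() - 0.5, centers.max() + 0.5, 60)
    curve = []
    for c in grid:
        y = _bump(x, c, cfg.bump_width)
        y = y - y.mean()
        nrm = np.linalg.norm(y)
        if nrm > 1e-9:
            curve.append(y / nrm)
    curve_arr = np.array(curve)
    size = max(1, cfg.scatter_module_size)
    n_modules = -(-n // size)
    mod_dirs = _draw_far_directions(
        n_modules, curve_arr, cfg.n_conditions, rng, cfg.scatter_max_curve_cos
    )
    assign = np.repeat(np.arange(n_modules), size)[:n]
    out = _draw_far_directions(
        n,
        curve_arr,
        cfg.n_conditions,
        rng,
        cfg.scatter_max_curve_cos,
        mix_with=mod_dirs[assign],
        mix_weight=cfg.scatter_module_cos,
    )
    sds = out.std(axis=1, keepdims=True)
    sds[sds == 0] = 1.0
    return out / sds


def simulate_timecourse(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the paired two-program dataset described in the module docs."""
    ss = np.random.SeedSequence(cfg.rng_seed)
    rng_genes, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))

    x = np.arange(1, cfg.n_conditions + 1, dtype=float)
    centers = _wave_centers(cfg)
    tfs = tf_gene_ids(cfg.n_waves, cfg.tfs_per_wave)

    n_nonexpr = int(round(cfg.frac_nonexpressed * cfg.n_background_genes))
    n_bg_expr = cfg.n_background_genes - n_nonexpr
    sc_ids = [f"TF_X{i:04d}" for i in range(1, cfg.n_scatter_tfs + 1)]
    bg_ids = [f"BG_{i:04d}" for i in range(1, n_bg_expr + 1)]
    hk_ids = [f"HK_{i:04d}" for i in range(1, cfg.n_housekeeping + 1)]
    ne_ids = [f"NE_{i:04d}" for i in range(1, n_nonexpr + 1)]

    genes = tfs + sc_ids + bg_ids + hk_ids + ne_ids
    index_of = {g: i for i, g in enumerate(genes)}
    amps = cfg.amplitude * np.exp(rng_genes.normal(0.0, cfg.amp_log_sd, size=len(genes)))
    # condition-level noise scale per gene, relative to its profile SD
    noise_scale = rng_genes.uniform(cfg.gene_noise_lo, cfg.gene_noise_hi, size=len(genes))
    if bg_ids:
        b0 = index_of[bg_ids[0]]
        noise_scale[b0 : b0 + len(bg_ids)] = rng_genes.uniform(
            cfg.bg_noise_lo, cfg.bg_noise_hi, size=len(bg_ids)
        )
    # the designated seed: first TF of wave 1, with a boosted amplitude so
    # the "highest-amplitude wave-1 TF" recommendation finds it
    seed_gene = "TF_W01_01"
    amps[index_of[seed_gene]] *= 3.0
    # stable per-gene shape components of the non-cascade TFs (shared
    # between programs): centered, unit population SD across conditions,
    # and rejected until well away from the wave-profile curve so that no
    # non-cascade TF can cross the co-expression cutoff with a wave gene
    scatter_dirs = _scatter_directions(len(sc_ids), centers, cfg, rng_genes)
    # non-cascade TFs get a tight amplitude spread so none of them is
    # quiet enough (relative to replicate noise) to mimic a wave profile
    if sc_ids:
        s0 = index_of[sc_ids[0]]
        amps[s0 : s0 + len(sc_ids)] = cfg.amplitude * np.exp(
            rng_genes.normal(0.0, 0.15, size=len(sc_ids))
        )
    # constitutive genes: a dense, tight block just above the bulk of the
    # expression distribution, so each sample's upper quartile falls inside
    # it and the normalization factor is pinned (shared quantile wobble
    # would otherwise correlate every flat gene with every other)
    hk_lo = index_of[hk_ids[0]] if hk_ids else len(genes)
    amps[hk_lo : hk_lo + len(hk_ids)] = (
        1.3 * cfg.amplitude * np.exp(rng_genes.normal(0.0, 0.01, size=len(hk_ids)))
    )
    bg_waves = rng_genes.integers(1, cfg.n_waves + 1, size=n_bg_expr)

    wave_a: dict[str, int] = {}
    wave_b: dict[str, int] = {}
    for tf in tfs:
        w = base_wave(tf)
        wave_a[tf], wave_b[tf] = cfg.shift_map.get(tf, (w, w))
    for g, w in zip(bg_ids, bg_waves):
        wave_a[g] = wave_b[g] = int(w)

    sample_cols = [
        (f"C{c}", f"C{c}_R{r}")
        for c in range(1, cfg.n_conditions + 1)
        for r in range(1, cfg.replicates + 1)
    ]

    # residual directions of the neighboring waves (what remains of wave
    # w+-1's profile after removing its projection on wave w's profile):
    # background-gene noise is kept away from these so spill into the
    # neighbor's gene set comes only from the sub-cutoff base correlation
    wave_vecs = []
    for ci in range(len(centers)):
        v = _bump(x, centers[ci], cfg.bump_width)
        v = v - v.mean()
        wave_vecs.append(v / np.linalg.norm(v))
    neighbor_resid: dict[int, np.ndarray] = {}
    for w in range(1, cfg.n_waves + 1):
        rows = []
        for nb in (w - 1, w + 1):
            if 1 <= nb <= cfg.n_waves:
                r_vec = wave_vecs[nb] - (wave_vecs[nb] @ wave_vecs[w]) * wave_vecs[w]
                nrm = np.linalg.norm(r_vec)
                if nrm > 1e-9:
                    rows.append(r_vec / nrm)
        neighbor_resid[w] = np.array(rows)

    bg_set = set(bg_ids)

    def one_program(waves: dict[str, int], rng: np.random.Generator, tag: str):
        data = np.empty((len(genes), len(sample_cols)))
        noise_gain = cfg.noise_sd_frac / 0.05  # both components vanish at 0
        hk = set(hk_ids)
        sc = {g: i for i, g in enumerate(sc_ids)}
        for gi, g in enumerate(genes):
            if g in waves or g in hk or g in sc:
                if g in hk:
                    mean = np.full_like(x, amps[gi])
                elif g in sc:
                    shape = 1.0 + cfg.scatter_shape_sd * scatter_dirs[sc[g]]
                    mean = np.maximum(amps[gi] * shape, 0.05 * amps[gi])
                else:
                    # centers[0] is the seed's leading position, centers[w]
                    # the center of wave w
                    ci = 0 if (g == seed_gene and waves[g] == 1) else waves[g]
                    mean = amps[gi] * (
                        cfg.baseline_frac + _bump(x, centers[ci], cfg.bump_width)
                    )
                    bio_sd = noise_scale[gi] * float(mean.std()) * noise_gain
                    is_bg = g in bg_set
                    avoid = neighbor_resid[waves[g]] if is_bg else None
                    mean = np.maximum(
                        mean
                        + _condition_noise(
                            mean, bio_sd, rng, avoid=avoid, exact=is_bg
                        ),
                        0.0,
                    )
                reps = np.repeat(mean, cfg.replicates)
                noise = rng.normal(0.0, cfg.noise_sd_frac * cfg.amplitude, size=reps.size)
                data[gi] = np.maximum(reps + noise, 0.0)
            else:
                data[gi] = rng.uniform(0.0, 0.9, size=len(sample_cols))
        cols = [f"{tag}_{s}" for _, s in sample_cols]
        matrix = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=cols))
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": cols,
                    "condition": [c for c, _ in sample_cols],
                    "order": [int(c[1:]) for c, _ in sample_cols],
                    "replicate": [s.split("_R")[1] for _, s in sample_cols],
                }
            )
        )
        return matrix, sheet

    matrix_a, sheet_a = one_program(wave_a, rng_a, "A")
    matrix_b, sheet_b = one_program(wave_b, rng_b, "B")

    def recommended_seed(waves: dict[str, int]) -> str:
        wave1 = [g for g in tfs if waves[g] == 1]
        return max(wave1, key=lambda g: amps[genes.index(g)])

    hk_set = set(hk_ids)
    tf_set = set(tfs) | set(sc_ids)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "wave_a": [wave_a.get(g, 0) for g in genes],
            "wave_b": [wave_b.get(g, 0) for g in genes],
            "is_tf": [g in tf_set for g in genes],
            "is_expressed": [g not in set(ne_ids) for g in genes],
        }
    )
    return SyntheticDataset(
        matrix_a,
        matrix_b,
        sheet_a,
        sheet_b,
        truth,
        tuple(tfs) + tuple(sc_ids),
        recommended_seed(wave_a),
        recommended_seed(wave_b),
        cfg,
    )


def wave_terms(d: SyntheticDataset) -> TermCollection:
    """A fixture GMT whose terms are the planted waves (program-A labels)."""
    names, members = {}, {}
    t = d.truth[d.truth["is_expressed"]]
    for w in range(1, d.config.n_waves + 1):
        genes = frozenset(t.loc[t["wave_a"] == w, "gene_id"])
        if genes:
            names[f"WAVE_{w:02d}"] = f"planted wave {w}"
            members[f"WAVE_{w:02d}"] = genes
    return TermCollection(names, members)


def write_fixture(d: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text fixture files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix_a": out / "matrix_A.tsv",
        "matrix_b": out / "matrix_B.tsv",
        "samples_a": out / "samples_A.tsv",
        "samples_b": out / "samples_B.tsv",
        "tf_list": out / "tf_list.txt",
        "truth": out / "truth.tsv",
        "gmt": out / "waves.gmt",
    }
    write_expression_matrix(d.matrix_a, paths["matrix_a"])
    write_expression_matrix(d.matrix_b, paths["matrix_b"])
    write_sample_sheet(d.sheet_a, paths["samples_a"])
    write_sample_sheet(d.sheet_b, paths["samples_b"])
    write_gene_list(d.tf_ids, paths["tf_list"])
    d.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_gmt(wave_terms(d), paths["gmt"])
    return paths
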