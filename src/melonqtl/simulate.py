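"""Synthetic phenotype, genotype, bulk-read and multi-study QTL generators.

The generators emulate the data structures of a melon sweetness breeding
program: a 20-parent half-diallel with additive + dominance + plot-noise
structure, single-seed-descent (SSD) inbred-line populations segregating for
planted total-soluble-solids (TSS) QTLs, extreme-tail selection, pooled
whole-genome resequencing of the tails at ~30x, and multi-study QTL interval
tables with shared hotspots.  Every generator takes an explicit integer seed
and is deterministic; there is no global random state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MELON_CHROM_SIZES",
    "DiallelTruth",
    "QTL",
    "BiparentalTruth",
    "LineGenotypes",
    "Hotspot",
    "simulate_diallel",
    "simulate_biparental",
    "select_tails",
    "simulate_bulk_reads",
    "simulate_qtl_studies",
    "qtl_marker_id",
]

# Approximate 12-chromosome melon karyotype (bp).  Sizes are realistic in
# scale (25-36 Mb each, 355 Mb total) and chosen so that a 5-Mb partition of
# the genome yields 75 bins, matching the published genome scale.
MELON_CHROM_SIZES: dict[str, int] = {
    "chr01": 35_000_000,
    "chr02": 26_000_000,
    "chr03": 30_000_000,
    "chr04": 34_000_000,
    "chr05": 28_000_000,
    "chr06": 36_000_000,
    "chr07": 26_000_000,
    "chr08": 32_000_000,
    "chr09": 25_000_000,
    "chr10": 25_000_000,
    "chr11": 33_000_000,
    "chr12": 25_000_000,
}

# genotype codes: dosage of the parent-A allele; -1 = missing
GENO_AA = 2
GENO_HET = 1
GENO_BB = 0
GENO_MISSING = -1

_CODE_TO_CHAR = {GENO_AA: "A", GENO_HET: "H", GENO_BB: "B", GENO_MISSING: "N"}
_CHAR_TO_CODE = {v: k for k, v in _CODE_TO_CHAR.items()}


@dataclass
class DiallelTruth:
    """Generative truth for a half-diallel trial.

    ``parent_values`` are parental genetic values in degrees Brix;
    ``dominance_deviations`` maps each unordered parent pair (i, j with
    i < j, 0-based indices) to the dominance deviation d of their F1 from
    the mid-parent value.  ``env_sd`` is the plot-noise standard deviation.
    """

    parent_values: list[float]
    dominance_deviations: dict[tuple[int, int], float] = field(default_factory=dict)
    env_sd: float = 1.0
    n_years: int = 3
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.parent_values) < 2:
            raise ValueError("a diallel needs at least 2 parents")
        if self.env_sd < 0:
            raise ValueError("env_sd must be non-negative")
        if self.n_years < 1 or self.n_reps < 1:
            raise ValueError("n_years and n_reps must be >= 1")
        pairs = set(itertools.combinations(range(len(self.parent_values)), 2))
        missing = pairs - set(self.dominance_deviations)
        # unspecified dominance deviations default to 0 (pure additivity)
        for p in missing:
            self.dominance_deviations[p] = 0.0

    @property
    def n_parents(self) -> int:
        return len(self.parent_values)

    def genetic_values(self) -> dict[str, float]:
        """Expected genetic value of every genotype (parents + F1s)."""
        vals = {parent_id(i): v for i, v in enumerate(self.parent_values)}
        for (i, j), d in sorted(self.dominance_deviations.items()):
            mid = (self.parent_values[i] + self.parent_values[j]) / 2.0
            vals[f1_id(i, j)] = mid + d
        return vals


def parent_id(i: int) -> str:
    return f"P{i + 1:02d}"


def f1_id(i: int, j: int) -> str:
    i, j = sorted((i, j))
    return f"{parent_id(i)}x{parent_id(j)}"


def simulate_diallel(truth: DiallelTruth, trait: str = "TSS") -> pd.DataFrame:
    """Simulate plot-level phenotypes for a half-diallel trial.

    Returns a long-format phenotype table with one record per genotype
    (parents and all unordered F1s) x year x replicate.  Each F1's expected
    value is its mid-parent value plus the pair's dominance deviation; each
    parent's expected value is its own genetic value.  Plot noise is i.i.d.
    Gaussian with standard deviation ``truth.env_sd``.
    """
    rng = np.random.default_rng(truth.seed)
    genetic = truth.genetic_values()
    geno_ids = list(genetic)
    n_g = len(geno_ids)
    classes = ["parent" if "x" not in g else "F1" for g in geno_ids]

    rows = []
    for year in range(1, truth.n_years + 1):
        for rep in range(1, truth.n_reps + 1):
            noise = rng.normal(0.0, truth.env_sd, n_g) if truth.env_sd > 0 else np.zeros(n_g)
            for g, cls, e in zip(geno_ids, classes, noise):
                rows.append((g, cls, year, rep, trait, genetic[g] + e))
    return pd.DataFrame(
        rows, columns=["line", "genotype_class", "year", "rep", "trait", "value"]
    )


def diallel_design(truth: DiallelTruth) -> pd.DataFrame:
    """Pedigree table for a half-diallel: genotype, p1, p2 (parents selfed)."""
    rows = [(parent_id(i), parent_id(i), parent_id(i)) for i in range(truth.n_parents)]
    rows += [
        (f1_id(i, j), parent_id(i), parent_id(j))
        for i, j in itertools.combinations(range(truth.n_parents), 2)
    ]
    return pd.DataFrame(rows, columns=["genotype", "p1", "p2"])


@dataclass(frozen=True)
class QTL:
    """A planted biallelic QTL: the two homozygote phenotype classes differ
    by ``effect`` degrees Brix, the increasing allele donated by ``donor``
    ('A' or 'B')."""

    chrom: str
    pos: int
    effect: float
    donor: str = "A"

    def __post_init__(self) -> None:
        if self.donor not in ("A", "B"):
            raise ValueError("QTL donor must be 'A' or 'B'")


@dataclass
class BiparentalTruth:
    """Generative truth for an SSD inbred-line population (e.g. F6 RILs)."""

    n_lines: int
    generation: int = 6
    qtls: list[QTL] = field(default_factory=list)
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if self.generation < 2:
            raise ValueError("generation must be >= 2 (F2 onward)")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")

    @property
    def expected_het(self) -> float:
        """Expected residual heterozygosity per locus: (1/2)^(generation-1)."""
        return 0.5 ** (self.generation - 1)


@dataclass
class LineGenotypes:
    """Line x marker genotype matrix, parent-of-origin coded.

    ``geno`` holds the dosage of the parent-A allele per line x marker
    (2 = hom A, 1 = het, 0 = hom B, -1 = missing); ``markers`` has columns
    marker, chrom, pos with positions strictly increasing per chromosome.
    """

    lines: list[str]
    markers: pd.DataFrame
    geno: np.ndarray

    def __post_init__(self) -> None:
        if self.geno.shape != (len(self.lines), len(self.markers)):
            raise ValueError("geno matrix shape does not match lines x markers")
        bad = ~np.isin(self.geno, [GENO_AA, GENO_HET, GENO_BB, GENO_MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {2, 1, 0, -1}")
        for _, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("marker positions must be strictly increasing per chromosome")

    def marker_index(self, marker: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker!r}")
        return int(idx[0])

    def column(self, marker: str) -> np.ndarray:
        return self.geno[:, self.marker_index(marker)]

    def to_frame(self) -> pd.DataFrame:
        """Lines x markers matrix with A/B/H/N character codes."""
        chars = np.vectorize(_CODE_TO_CHAR.get)(self.geno)
        return pd.DataFrame(chars, index=self.lines, columns=self.markers["marker"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, markers: pd.DataFrame) -> "LineGenotypes":
        geno = np.vectorize(_CHAR_TO_CODE.get)(frame.to_numpy())
        return cls(list(frame.index), markers.reset_index(drop=True), geno.astype(np.int8))


def qtl_marker_id(chrom: str, pos: int) -> str:
    """Marker id used for a planted QTL site in simulated genotype matrices."""
    return f"{chrom}:{pos}"


def _marker_grid(chrom_sizes: dict[str, int], n_per_chrom: int) -> dict[str, np.ndarray]:
    return {
        c: np.round(np.linspace(1, L, n_per_chrom + 2)[1:-1]).astype(np.int64)
        for c, L in chrom_sizes.items()
    }


def _simulate_ssd_chrom(
    rng: np.random.Generator, n_lines: int, pos: np.ndarray, length: int, generation: int
) -> np.ndarray:
    """Simulate SSD inheritance of one chromosome for all lines at once.

    Each line descends from an F1 carrying one parent-A and one parent-B
    haplotype.  Every meiosis places exactly one crossover uniformly along
    the chromosome (map-distance proxy); each selfing draws two independent
    gametes.  Returns the dosage of the A allele (n_lines x n_pos).
    """
    n_pos = len(pos)
    hap1 = np.ones((n_lines, n_pos), dtype=bool)   # True = A allele
    hap2 = np.zeros((n_lines, n_pos), dtype=bool)
    for _ in range(generation - 1):  # F1 -> F(generation)
        new = []
        for _g in range(2):
            xover = rng.uniform(0, length, n_lines)
            start_first = rng.random(n_lines) < 0.5
            before = pos[None, :] < xover[:, None]
            first = np.where(start_first[:, None], hap1, hap2)
            second = np.where(start_first[:, None], hap2, hap1)
            new.append(np.where(before, first, second))
        hap1, hap2 = new
    return hap1.astype(np.int8) + hap2.astype(np.int8)


def simulate_biparental(
    truth: BiparentalTruth,
    chrom_sizes: dict[str, int] | None = None,
    n_markers_per_chrom: int = 100,
    baseline: float = 10.0,
    trait: str = "TSS",
    missing_rate: float = 0.0,
) -> tuple[LineGenotypes, pd.DataFrame]:
    """Simulate an SSD inbred-line population with planted QTLs.

    Markers are laid on an even grid per chromosome; each planted QTL is
    inserted as an additional marker at its position (id per
    :func:`qtl_marker_id`), so linkage between the QTL and flanking markers
    emerges from the shared crossover process.  The phenotype of a line is
    ``baseline`` + the sum of signed QTL contributions + Gaussian noise whose
    variance is calibrated against the *realized* genetic variance so the
    line-level broad-sense heritability matches ``truth.h2`` in each draw.
    """
    chrom_sizes = dict(chrom_sizes or MELON_CHROM_SIZES)
    for q in truth.qtls:
        if q.chrom not in chrom_sizes:
            raise ValueError(f"QTL chromosome {q.chrom!r} not in chrom_sizes")
        if not 1 <= q.pos <= chrom_sizes[q.chrom]:
            raise ValueError(f"QTL position {q.pos} outside {q.chrom}")

    rng = np.random.default_rng(truth.seed)
    grid = _marker_grid(chrom_sizes, n_markers_per_chrom)
    qtl_pos: dict[str, set[int]] = {}
    for q in truth.qtls:
        qtl_pos.setdefault(q.chrom, set()).add(q.pos)

    lines = [f"L{i + 1:03d}" for i in range(truth.n_lines)]
    marker_rows = []
    geno_cols = []
    qtl_dosage: dict[tuple[str, int], np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        pos = np.union1d(grid[chrom], np.array(sorted(qtl_pos.get(chrom, ())), dtype=np.int64))
        dose = _simulate_ssd_chrom(rng, truth.n_lines, pos, length, truth.generation)
        for k, p in enumerate(pos):
            marker_rows.append((qtl_marker_id(chrom, int(p)), chrom, int(p)))
            if int(p) in qtl_pos.get(chrom, ()):
                qtl_dosage[(chrom, int(p))] = dose[:, k].copy()
        geno_cols.append(dose)
    geno = np.concatenate(geno_cols, axis=1)

    # genetic values from planted QTLs: hom donor vs hom other differ by effect
    g = np.zeros(truth.n_lines)
    for q in truth.qtls:
        dose_a = qtl_dosage[(q.chrom, q.pos)].astype(float)
        sign = 1.0 if q.donor == "A" else -1.0
        g += sign * (dose_a - 1.0) * (q.effect / 2.0)

    var_g = float(np.var(g))
    if truth.h2 >= 1.0:
        noise_sd = 0.0
    elif var_g == 0.0:
        noise_sd = 1.0  # no segregating genetic variance: unit plot noise
    else:
        noise_sd = float(np.sqrt(var_g * (1.0 - truth.h2) / truth.h2))
    values = baseline + g + (rng.normal(0.0, noise_sd, truth.n_lines) if noise_sd > 0 else 0.0)

    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno = np.where(mask, GENO_MISSING, geno)

    markers = pd.DataFrame(marker_rows, columns=["marker", "chrom", "pos"])
    genos = LineGenotypes(lines, markers, geno.astype(np.int8))
    pheno = pd.DataFrame(
        {
            "line": lines,
            "genotype_class": "line",
            "year": 1,
            "rep": 1,
            "trait": trait,
            "value": values,
        }
    )
    return genos, pheno


def line_means(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Per-line mean of a trait over years/replicates."""
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from phenotype table")
    return sub.groupby("line")["value"].mean()


def select_tails(
    pheno: pd.DataFrame, trait: str, n_high: int, n_low: int
) -> tuple[list[str], list[str]]:
    """Select the extreme-phenotype tails of a population by line means.

    Returns the ``n_high`` top and ``n_low`` bottom lines; ties are broken
    by lexical line id, and the two sets are disjoint by construction.
    """
    means = line_means(pheno, trait)
    if n_high + n_low > len(means):
        raise ValueError(
            f"requested {n_high}+{n_low} tails from only {len(means)} lines"
        )
    order = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    low = [k for k, _ in order[:n_low]]
    high = [k for k, _ in order[-n_high:]][::-1] if n_high else []
    return high, low


def simulate_bulk_reads(
    genos: LineGenotypes,
    high_ids: list[str],
    low_ids: list[str],
    n_sites: int,
    depth_mean: float = 30.0,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Simulate pooled short-read allele depths over two tail bulks.

    Sites are placed uniformly along each chromosome (count proportional to
    length); the genotype of a line at a site is that of its nearest marker,
    a dense-SNP proxy for the line's local haplotype.  Per site and bulk the
    reference(-parent-A)-allele frequency is the mean A-allele dosage/2 over
    the bulk's lines (het = 0.5, missing excluded), read depth is
    Poisson(``depth_mean``) and reference reads Binomial(depth, frequency).
    """
    if not high_ids or not low_ids:
        raise ValueError("both bulks must be non-empty")
    unknown = (set(high_ids) | set(low_ids)) - set(genos.lines)
    if unknown:
        raise ValueError(f"bulk ids not in genotype table: {sorted(unknown)[:3]}...")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    chrom_sizes = dict(chrom_sizes or MELON_CHROM_SIZES)

    rng = np.random.default_rng(seed)
    line_idx = {l: i for i, l in enumerate(genos.lines)}
    bulks = {
        "high": np.array([line_idx[l] for l in high_ids]),
        "low": np.array([line_idx[l] for l in low_ids]),
    }

    total = sum(chrom_sizes.values())
    out = []
    for chrom, length in chrom_sizes.items():
        k = int(round(n_sites * length / total))
        if k == 0:
            continue
        pos = np.sort(rng.integers(1, length + 1, k))
        sub = genos.markers[genos.markers["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no markers on {chrom}")
        mpos = sub["pos"].to_numpy()
        mcols = sub.index.to_numpy()
        # nearest marker (ties -> left)
        right = np.searchsorted(mpos, pos)
        left = np.clip(right - 1, 0, len(mpos) - 1)
        right = np.clip(right, 0, len(mpos) - 1)
        pick = np.where(np.abs(mpos[right] - pos) < np.abs(pos - mpos[left]), right, left)
        cols = mcols[pick]

        freqs = {}
        for name, idx in bulks.items():
            dose = genos.geno[np.ix_(idx, cols)].astype(float)
            dose[dose == GENO_MISSING] = np.nan
            with np.errstate(invalid="ignore"):
                f = np.nanmean(dose / 2.0, axis=0)
            freqs[name] = np.nan_to_num(f, nan=0.5)
        depth_h = rng.poisson(depth_mean, k)
        depth_l = rng.poisson(depth_mean, k)
        ref_h = rng.binomial(depth_h, freqs["high"])
        ref_l = rng.binomial(depth_l, freqs["low"])
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref_high": ref_h,
                    "total_high": depth_h,
                    "ref_low": ref_l,
                    "total_low": depth_l,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class Hotspot:
    """A genomic bin emitting a QTL in each study with probability ``prob``."""

    chrom: str
    start: int
    end: int
    prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("hotspot probability must lie in [0, 1]")
        if self.start > self.end:
            raise ValueError("hotspot start > end")


def simulate_qtl_studies(
    n_studies: int,
    chrom_sizes: dict[str, int],
    hotspots: list[Hotspot],
    background_rate: float = 2.0,
    length_range: tuple[int, int] = (500_000, 8_000_000),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate QTL interval tables from many independent mapping studies.

    Each study emits, per hotspot, an interval centred in the hotspot bin
    with probability ``Hotspot.prob`` (length drawn uniformly from
    ``length_range``), plus Poisson(``background_rate``) background QTLs
    placed uniformly on the genome.  Returns the records table (study,
    trait, chrom, start, end, donor) and a truth-bookkeeping dict with
    per-study emitted counts and per-hotspot emitting studies.
    """
    for h in hotspots:
        if h.chrom not in chrom_sizes or h.end > chrom_sizes[h.chrom]:
            raise ValueError(f"hotspot {h} outside chromosome bounds")
    if length_range[0] <= 0:
        raise ValueError("interval lengths must be positive")

    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    rows = []
    per_study_counts: dict[str, int] = {}
    hotspot_studies: dict[int, list[str]] = {i: [] for i in range(len(hotspots))}
    for s in range(1, n_studies + 1):
        study = f"S{s:02d}"
        count = 0
        for i, h in enumerate(hotspots):
            if rng.random() < h.prob:
                centre = (h.start + h.end) // 2
                length = int(rng.integers(length_range[0], length_range[1] + 1))
                start = max(1, centre - length // 2)
                end = min(chrom_sizes[h.chrom], start + length - 1)
                donor = "high" if rng.random() < 0.5 else "low"
                rows.append((study, "TSS", h.chrom, start, end, donor))
                hotspot_studies[i].append(study)
                count += 1
        for _ in range(rng.poisson(background_rate)):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            start = int(rng.integers(1, max(2, chrom_sizes[chrom] - length + 1)))
            end = min(chrom_sizes[chrom], start + length - 1)
            donor = "high" if rng.random() < 0.5 else "low"
            rows.append((study, "TSS", chrom, start, end, donor))
            count += 1
        per_study_counts[study] = count

    records = pd.DataFrame(
        rows, columns=["study", "trait", "chrom", "start", "end", "donor"]
    )
    truth = {"per_study_counts": per_study_counts, "hotspot_studies": hotspot_studies}
    return records, truth
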