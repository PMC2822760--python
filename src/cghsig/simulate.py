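"""Synthetic aCGH cohort generator.

Generates fluorescence-ratio (FR) cohorts with the statistical structure the
downstream analysis assumes: a diploid baseline near FR = 1, segmental copy
number events attenuated by clonal fraction, class-specific signature
deletions confined to lymphoid blast-crisis samples, polymorphic CNV loci
shared across classes, and per-sample Gaussian noise on the simple-ratio
scale. Every cohort comes with a truth set for recovery testing.

The ratio model: a test sample with ``c`` extra copies (``c`` may be
negative) in a fraction ``f`` of cells, hybridised against a diploid
reference, yields an expected simple ratio ``(2 + c*f) / 2``. Independent
events on the same sample compose additively in ``c*f`` space. Sex
chromosomes are simulated against a sex-mixed pooled reference (X dosage
1.5, Y dosage 0.5), which makes them systematically off-ratio — the reason
the analysis pipeline, like the study design it emulates, drops them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ProbeGrid, merge_intervals
from .vocab import LYMPHOID_CLASSES, SAMPLE_CLASSES

VALID_COPY_CHANGES = (-2, -1, 1, 2)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def expected_ratio(copy_change: int, clonal_fraction: float) -> float:
    """Expected test/reference simple ratio for a diploid reference.

    Parameters
    ----------
    copy_change : int
        Copies gained (+) or lost (-) relative to diploid; one of
        ``{-2, -1, +1, +2}``.
    clonal_fraction : float
        Fraction of cells in the sample carrying the event, in ``(0, 1]``.

    Returns
    -------
    float
        ``(2 + copy_change * clonal_fraction) / 2``. A homozygous loss at
        full clonality returns 0.0.
    """
    if copy_change not in VALID_COPY_CHANGES:
        raise ConfigError(f"copy_change must be in {VALID_COPY_CHANGES}, "
                          f"got {copy_change!r}")
    if not (0.0 < clonal_fraction <= 1.0):
        raise ConfigError(f"clonal_fraction must be in (0, 1], "
                          f"got {clonal_fraction!r}")
    return (2.0 + copy_change * clonal_fraction) / 2.0


@dataclass(frozen=True)
class AberrationEvent:
    """A planted copy number event on a set of samples."""

    chrom: str
    start: int
    end: int
    copy_change: int
    clonal_fraction: float
    sample_ids: frozenset[str]
    name: str = ""
    kind: str = "signature"        # "signature" or "cnv"
    role: str = ""                 # "primary" / "secondary" for signatures

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError(f"event {self.name!r}: end <= start")
        if self.copy_change not in VALID_COPY_CHANGES:
            raise ConfigError(f"event {self.name!r}: bad copy_change")
        if not (0.0 < self.clonal_fraction <= 1.0):
            raise ConfigError(f"event {self.name!r}: bad clonal_fraction")


@dataclass(frozen=True)
class SignatureTemplate:
    """A named region deleted (or gained) in lymphoid-class samples.

    ``carrier`` selects which lymphoid samples receive the event:
    ``"all"`` plants it in every lymphoid sample; ``"concomitant"`` plants
    it in the shared concomitant subset (the same subset for all such
    templates, emulating joint segmental loss).
    """

    name: str
    chrom: str
    start: int
    end: int
    role: str = "primary"          # "primary" or "secondary"
    copy_change: int = -2
    carrier: str = "all"           # "all" or "concomitant"


@dataclass(frozen=True)
class CnvLocus:
    """A polymorphic copy-number-variable locus, class-agnostic."""

    chrom: str
    start: int
    end: int
    frequency: float
    copy_change: int = -1


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int
    genome_spec: tuple[tuple[str, int], ...]
    class_counts: tuple[tuple[str, int], ...]
    noise_sd_range: tuple[float, float] = (0.057, 0.187)
    cnv_loci: tuple[CnvLocus, ...] = ()
    signature_regions: tuple[SignatureTemplate, ...] = ()
    n_concomitant: int = 7
    clonal_fraction_range: tuple[float, float] = (0.8, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.noise_sd_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("noise_sd_range must satisfy 0 < lo <= hi < 1")
        for cls, n in self.class_counts:
            if cls not in SAMPLE_CLASSES:
                raise ConfigError(f"unknown sample class {cls!r}")
            if n < 0:
                raise ConfigError("class counts must be non-negative")
        for locus in self.cnv_loci:
            if not (0.0 <= locus.frequency <= 1.0):
                raise ConfigError("CNV frequency must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.class_counts)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TruthSet:
    """Planted ground truth of a simulated cohort."""

    events: tuple[AberrationEvent, ...]
    samples: pd.DataFrame = field(repr=False)   # sample_id, class, sex, noise_sd
    seed: int = 0

    def events_frame(self) -> pd.DataFrame:
        """One row per (event, sample): the on-disk truth representation."""
        rows = []
        for ev in self.events:
            for sid in sorted(ev.sample_ids):
                rows.append((ev.name, ev.kind, ev.role, ev.chrom, ev.start,
                             ev.end, ev.copy_change, ev.clonal_fraction, sid))
        return pd.DataFrame(rows, columns=[
            "name", "kind", "role", "chrom", "start", "end",
            "copy_change", "clonal_fraction", "sample_id"])

    def signature_probe_rows(self, grid: ProbeGrid) -> np.ndarray:
        """Row indices of probes covered by any planted signature event."""
        regions = {(ev.chrom, ev.start, ev.end)
                   for ev in self.events if ev.kind == "signature"}
        rows: set[int] = set()
        for chrom, s, e in regions:
            rows.update(grid.probes_in(chrom, s, e).tolist())
        return np.array(sorted(rows), dtype=np.int64)

    def region_carrier_counts(self) -> pd.DataFrame:
        """Planted per-region carrier counts among signature events."""
        df = self.events_frame()
        df = df[df["kind"] == "signature"]
        out = (df.groupby(["name", "role"])["sample_id"].nunique()
                 .rename("n_carriers").reset_index())
        return out


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort bundle: inputs to the analysis plus the truth."""

    grid: ProbeGrid
    fr: pd.DataFrame = field(repr=False)        # probes x samples
    samples: pd.DataFrame = field(repr=False)   # sample_id, class, sex
    cnv_mask: pd.DataFrame = field(repr=False)  # merged chrom/start/end
    truth: TruthSet = field(repr=False)
    n_clipped_expected: int = 0
    n_clipped_noisy: int = 0


# ---------------------------------------------------------------------------
# probe grid construction
# ---------------------------------------------------------------------------

_PROBE_LENGTH = 60   # Agilent-style 60-mer footprint


def build_probe_grid(genome_spec, n_probes: int, seed: int) -> ProbeGrid:
    """Lay out ``n_probes`` across a genome, evenly spaced with jitter.

    Probes are allocated to chromosomes proportionally to length using
    largest-remainder rounding, then placed at jittered regular intervals.
    Deterministic given ``seed``.
    """
    genome_spec = [(str(c), int(length)) for c, length in genome_spec]
    if n_probes < 2:
        raise ConfigError("n_probes must be >= 2")
    if not genome_spec or any(length <= 0 for _, length in genome_spec):
        raise ConfigError("genome lengths must be positive")
    rng = np.random.default_rng(seed)
    total = sum(length for _, length in genome_spec)
    quotas = np.array([n_probes * length / total for _, length in genome_spec])
    counts = np.floor(quotas).astype(int)
    remainder = n_probes - counts.sum()
    if remainder:
        frac_order = np.argsort(-(quotas - counts), kind="stable")
        counts[frac_order[:remainder]] += 1
    rows = []
    k = 0
    for (chrom, length), c in zip(genome_spec, counts):
        if c == 0:
            continue
        spacing = length / c
        centers = (np.arange(c) + 0.5) * spacing
        jitter = rng.uniform(-0.2, 0.2, size=c) * spacing
        starts = np.clip(np.round(centers + jitter).astype(np.int64),
                         0, max(0, length - _PROBE_LENGTH))
        # enforce strictly increasing starts (min gap 1 bp) while keeping
        # already-increasing positions untouched
        offs = np.arange(c, dtype=np.int64)
        starts = np.maximum.accumulate(starts - offs) + offs
        if starts[-1] >= length:
            raise ConfigError(f"too many probes for chromosome {chrom}")
        ends = np.minimum(starts + _PROBE_LENGTH, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), f"P{k:06d}", None))
            k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id",
                                     "gene"])
    return ProbeGrid(df)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _sample_sheet(config: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cls, n in config.class_counts:
        for i in range(n):
            rows.append((f"{cls}{i + 1:02d}", cls,
                         "M" if rng.random() < 0.5 else "F"))
    return pd.DataFrame(rows, columns=["sample_id", "class", "sex"])


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate an aCGH cohort and its truth set.

    The FR of probe *p* in sample *s* is the expected ratio of the copy
    state implied by all events covering *p* in *s* (summed in
    copy-change x clonal-fraction space), plus ``N(0, sd_s^2)`` noise with
    ``sd_s`` drawn uniformly from ``noise_sd_range``. Negative expected
    ratios and negative noisy ratios are clipped to 0 and counted.
    Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    grid = build_probe_grid(config.genome_spec, config.n_probes,
                            seed=int(rng.integers(2 ** 31)))
    samples = _sample_sheet(config, rng)
    n_s = len(samples)
    noise_sd = rng.uniform(*config.noise_sd_range, size=n_s)

    lymphoid = samples.loc[samples["class"].isin(LYMPHOID_CLASSES),
                           "sample_id"].tolist()
    if any(t.carrier == "concomitant" for t in config.signature_regions):
        n_cc = min(config.n_concomitant, len(lymphoid))
        concomitant = sorted(rng.choice(lymphoid, size=n_cc, replace=False))
    else:
        concomitant = []

    col_of = {sid: j for j, sid in enumerate(samples["sample_id"])}
    delta = np.zeros((len(grid), n_s))         # sum of copy_change * cf
    events: list[AberrationEvent] = []
    gene = grid.df["gene"].copy()

    for tmpl in config.signature_regions:
        carriers = lymphoid if tmpl.carrier == "all" else concomitant
        probe_rows = grid.probes_in(tmpl.chrom, tmpl.start, tmpl.end)
        gene.iloc[probe_rows] = tmpl.name
        for sid in carriers:
            cf = float(rng.uniform(*config.clonal_fraction_range))
            delta[np.ix_(probe_rows, [col_of[sid]])] += tmpl.copy_change * cf
            events.append(AberrationEvent(
                tmpl.chrom, tmpl.start, tmpl.end, tmpl.copy_change, cf,
                frozenset({sid}), name=tmpl.name, kind="signature",
                role=tmpl.role))

    for i, locus in enumerate(config.cnv_loci):
        carriers = samples.loc[rng.random(n_s) < locus.frequency,
                               "sample_id"].tolist()
        probe_rows = grid.probes_in(locus.chrom, locus.start, locus.end)
        cols = [col_of[s] for s in carriers]
        if cols:
            delta[np.ix_(probe_rows, cols)] += locus.copy_change * 1.0
        if carriers:
            events.append(AberrationEvent(
                locus.chrom, locus.start, locus.end, locus.copy_change, 1.0,
                frozenset(carriers), name=f"CNV{i + 1:02d}", kind="cnv"))

    grid = ProbeGrid(grid.df.assign(gene=gene))

    # baseline copy state: 2 on autosomes; sex chromosomes measured against
    # a sex-mixed pooled reference (X dosage 1.5, Y dosage 0.5)
    expected = (2.0 + delta) / 2.0
    chroms = grid.df["chrom"].to_numpy()
    is_male = (samples["sex"] == "M").to_numpy()
    x_rows = np.isin(chroms, ("chrX", "X"))
    y_rows = np.isin(chroms, ("chrY", "Y"))
    if x_rows.any():
        x_copies = np.where(is_male, 1.0, 2.0)
        expected[x_rows, :] = (x_copies + delta[x_rows, :]) / 1.5
    if y_rows.any():
        y_copies = np.where(is_male, 1.0, 0.0)
        expected[y_rows, :] = (y_copies + delta[y_rows, :]) / 0.5

    n_clip_exp = int((expected < 0).sum())
    expected = np.clip(expected, 0.0, None)
    fr_values = expected + rng.standard_normal(expected.shape) * noise_sd
    n_clip_noisy = int((fr_values < 0).sum())
    fr_values = np.clip(fr_values, 0.0, None)

    fr = pd.DataFrame(fr_values, index=grid.probe_ids,
                      columns=samples["sample_id"].tolist())
    fr.index.name = "probe_id"
    cnv_mask = merge_intervals(
        [(l.chrom, l.start, l.end) for l in config.cnv_loci])
    truth = TruthSet(
        events=tuple(events),
        samples=samples.assign(noise_sd=noise_sd),
        seed=config.seed)
    return Cohort(grid=grid, fr=fr, samples=samples, cnv_mask=cnv_mask,
                  truth=truth, n_clipped_expected=n_clip_exp,
                  n_clipped_noisy=n_clip_noisy)


# ---------------------------------------------------------------------------
# stock configurations
# ---------------------------------------------------------------------------

_MB = 1_000_000

#: reduced 8-chromosome genome used by the bundled demo and the test suite;
#: region widths are sized so each signature locus carries the same probe
#: multiplicity as its full-scale counterpart at the demo probe density.
DEMO_GENOME = (
    ("chr1", 200 * _MB), ("chr2", 190 * _MB), ("chr7", 159 * _MB),
    ("chr9", 141 * _MB), ("chr14", 107 * _MB), ("chr22", 51 * _MB),
    ("chrX", 155 * _MB), ("chrY", 57 * _MB),
)

DEMO_SIGNATURE = (
    SignatureTemplate("IGH", "chr14", 105_000_000, 105_600_000, "primary"),
    SignatureTemplate("TCRAD", "chr14", 21_700_000, 22_100_000, "primary"),
    SignatureTemplate("TCRG", "chr7", 38_000_000, 38_550_000, "primary"),
    SignatureTemplate("IKZF1", "chr7", 50_000_000, 50_350_000, "primary"),
    SignatureTemplate("7p_concomitant", "chr7", 28_000_000, 36_000_000,
                      "secondary", carrier="concomitant"),
    SignatureTemplate("9p_concomitant", "chr9", 5_000_000, 25_000_000,
                      "secondary", carrier="concomitant"),
)

DEMO_CNV = (
    CnvLocus("chr14", 105_700_000, 105_950_000, 0.30, -1),
    CnvLocus("chr14", 106_100_000, 106_300_000, 0.20, +1),
    CnvLocus("chr2", 88_000_000, 89_000_000, 0.25, -1),
    CnvLocus("chr22", 22_000_000, 22_500_000, 0.20, +1),
    CnvLocus("chr1", 150_000_000, 150_800_000, 0.15, -1),
)

#: the 74-sample two-class analysis cohort: 12 lymphoid vs 62 others
DEMO_CLASS_COUNTS = (
    ("CP", 31), ("AP", 2), ("BCL", 10), ("BCM", 15), ("BCmix", 2),
    ("control", 14),
)

#: the full 92-sample cohort (78 CML + 14 controls)
FULL_CLASS_COUNTS = (
    ("CP", 31), ("AP", 6), ("BCL", 10), ("BCM", 15), ("BCmix", 2),
    ("unclassified", 14), ("control", 14),
)

FULL_GENOME = tuple(
    (f"chr{i + 1}", mb * _MB) for i, mb in enumerate(
        (247, 243, 199, 191, 181, 171, 159, 146, 140, 135, 134, 132,
         114, 106, 100, 89, 79, 76, 63, 62, 47, 50))
) + (("chrX", 155 * _MB), ("chrY", 58 * _MB))

FULL_SIGNATURE = (
    SignatureTemplate("IGH", "chr14", 105_350_000, 105_500_000, "primary"),
    SignatureTemplate("TCRAD", "chr14", 21_950_000, 22_050_000, "primary"),
    SignatureTemplate("TCRG", "chr7", 38_250_000, 38_400_000, "primary"),
    SignatureTemplate("IKZF1", "chr7", 50_300_000, 50_450_000, "primary"),
    SignatureTemplate("7p_concomitant", "chr7", 28_000_000, 36_000_000,
                      "secondary", carrier="concomitant"),
    SignatureTemplate("9p_concomitant", "chr9", 5_000_000, 25_000_000,
                      "secondary", carrier="concomitant"),
)


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale cohort: 10,000 probes, 74 samples (12 lymphoid vs 62)."""
    base = dict(n_probes=10_000, genome_spec=DEMO_GENOME,
                class_counts=DEMO_CLASS_COUNTS, cnv_loci=DEMO_CNV,
                signature_regions=DEMO_SIGNATURE, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Pure-noise cohort: demo layout, no planted events of any kind."""
    return demo_config(seed=seed, cnv_loci=(), signature_regions=(),
                       **overrides)


def full_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale cohort: 105,000 probes, 24 chromosomes, 92 samples."""
    base = dict(n_probes=105_000, genome_spec=FULL_GENOME,
                class_counts=FULL_CLASS_COUNTS, cnv_loci=DEMO_CNV,
                signature_regions=FULL_SIGNATURE, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)
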