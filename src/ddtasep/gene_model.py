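"""Gene lattice geometry and rate-parameter construction.

The gene is discretized into 50-bp lattice sites grouped into repeating
*nucleosome units*: ``k_L`` linker site(s) followed by ``k_N``
nucleosome-associated sites (defaults 1 and 3, i.e. a 200-bp repeat with a
147-bp nucleosome and one 50-bp linker).  Site labels are 1-based in all
user-facing structures; site 1 is the transcription start site and is
always a linker site.

Sequence heterogeneity enters in two ways:

* *static defects* — per-site advance rates ``q_i`` drawn from local GC
  content (GC-rich DNA is slower) and optionally further slowed on
  annotated regions (CpG island, exons);
* *dynamic defects* — per-nucleosome wrap/unwrap rates ``h_c,m`` /
  ``h_o,m`` drawn from the GC content of the wrapped 150 bp, optionally
  stabilized (faster wrapping, slower unwrapping) on annotated regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_BP = 50

__all__ = [
    "SITE_BP",
    "NucleosomeUnit",
    "GeneGeometry",
    "RateParams",
    "RegionAnnotation",
    "build_uniform_gene",
    "uniform_rates",
    "sample_gc_advance_rates",
    "apply_static_defects",
    "sample_gc_nucleosome_rates",
    "apply_dynamic_defects",
    "default_annotated_gene",
    "geometry_table",
    "rates_tables",
    "geometry_from_table",
]


@dataclass(frozen=True)
class NucleosomeUnit:
    """One linker-plus-nucleosome repeat.  Site labels are 1-based."""

    index: int
    linker_sites: tuple[int, ...]
    nuc_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        ns = self.nuc_sites
        if list(ns) != list(range(ns[0], ns[0] + len(ns))):
            raise ValueError("nucleosome-associated sites must be contiguous")
        if self.linker_sites and ns[0] != self.linker_sites[-1] + 1:
            raise ValueError("nucleosome sites must immediately follow the linker sites")


@dataclass(frozen=True)
class GeneGeometry:
    """Lattice layout of a gene: ``N_h`` repeats of ``k_L`` linker + ``k_N`` nucleosome sites."""

    n_sites: int
    units: tuple[NucleosomeUnit, ...]
    k_L: int = 1
    k_N: int = 3
    site_bp: int = SITE_BP

    def __post_init__(self) -> None:
        if self.n_sites != self.n_units * (self.k_L + self.k_N):
            raise ValueError("n_sites must equal N_h * (k_L + k_N)")
        flat = [s for u in self.units for s in (*u.linker_sites, *u.nuc_sites)]
        if flat != list(range(1, self.n_sites + 1)):
            raise ValueError("units must tile sites 1..n_sites exactly")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def length_bp(self) -> int:
        return self.n_sites * self.site_bp

    # --- 0-based helper arrays used by the simulation engine -------------
    def entry_sites(self) -> np.ndarray:
        """0-based index of the first nucleosome-associated site of each unit."""
        return np.array([u.nuc_sites[0] - 1 for u in self.units], dtype=np.int32)

    def nuc_unit_of_site(self) -> np.ndarray:
        """For each 0-based site, owning unit if nucleosome-associated, else -1."""
        out = np.full(self.n_sites, -1, dtype=np.int32)
        for m, u in enumerate(self.units):
            for s in u.nuc_sites:
                out[s - 1] = m
        return out

    def gate_unit_of_site(self) -> np.ndarray:
        """For each 0-based site, unit whose wrap state gates entry into it, else -1."""
        out = np.full(self.n_sites, -1, dtype=np.int32)
        for m, u in enumerate(self.units):
            out[u.nuc_sites[0] - 1] = m
        return out

    def is_linker(self) -> np.ndarray:
        return self.nuc_unit_of_site() < 0


@dataclass
class RateParams:
    """Propensities of the model, in units where the nominal advance rate q sets the clock.

    ``q_site`` has one entry per lattice site; ``h_c_m``/``h_o_m`` one per
    nucleosome unit.  ``beta`` defaults to ``q`` in the model formulation.
    """

    alpha: float
    beta: float
    q_site: np.ndarray
    h_c_m: np.ndarray
    h_o_m: np.ndarray

    def __post_init__(self) -> None:
        self.q_site = np.asarray(self.q_site, dtype=float)
        self.h_c_m = np.asarray(self.h_c_m, dtype=float)
        self.h_o_m = np.asarray(self.h_o_m, dtype=float)
        for name in ("alpha", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("q_site", "h_c_m", "h_o_m"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"all {name} entries must be >= 0")


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled stretch of the gene (CpG island or exon), 1-based inclusive site range."""

    label: str
    site_range: tuple[int, int]
    nucleosome_indices: tuple[int, ...] = field(default=())

    def sites(self) -> range:
        return range(self.site_range[0], self.site_range[1] + 1)


def _check_regions(regions: list[RegionAnnotation], n_sites: int | None = None) -> None:
    covered: set[int] = set()
    for r in regions:
        lo, hi = r.site_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid site range {r.site_range}")
        if n_sites is not None and hi > n_sites:
            raise ValueError(f"region {r.label} exceeds the gene ({hi} > {n_sites})")
        s = set(r.sites())
        if covered & s:
            raise ValueError("regions may not overlap")
        covered |= s


def build_uniform_gene(length_bp: int, k_L: int = 1, k_N: int = 3) -> GeneGeometry:
    """Build a uniform gene of ``length_bp`` base pairs.

    The length must be divisible by ``50 * (k_L + k_N)`` so the lattice
    tiles exactly into nucleosome units; e.g. a 20-kbp gene with the
    default geometry gives 400 sites and 100 nucleosomes.
    """
    if k_L < 1 or k_N < 1:
        raise ValueError("k_L and k_N must be >= 1 (site 1 must be a linker)")
    repeat_bp = SITE_BP * (k_L + k_N)
    if length_bp <= 0 or length_bp % repeat_bp:
        raise ValueError(
            f"gene length {length_bp} bp is not divisible by the "
            f"{repeat_bp} bp nucleosome-unit repeat ({SITE_BP} bp x (k_L={k_L} + k_N={k_N}))"
        )
    n_units = length_bp // repeat_bp
    units = []
    s = 1
    for m in range(n_units):
        linkers = tuple(range(s, s + k_L))
        nucs = tuple(range(s + k_L, s + k_L + k_N))
        units.append(NucleosomeUnit(m + 1, linkers, nucs))
        s += k_L + k_N
    return GeneGeometry(n_sites=n_units * (k_L + k_N), units=tuple(units), k_L=k_L, k_N=k_N)


def uniform_rates(
    geom: GeneGeometry,
    alpha: float,
    beta: float,
    q: float = 1.0,
    h_c: float = 0.0,
    h_o: float = 1.0,
) -> RateParams:
    """Broadcast scalar rates over the lattice (the homogeneous model)."""
    if min(alpha, beta, q, h_c, h_o) < 0:
        raise ValueError("rates must be >= 0")
    return RateParams(
        alpha=alpha,
        beta=beta,
        q_site=np.full(geom.n_sites, float(q)),
        h_c_m=np.full(geom.n_units, float(h_c)),
        h_o_m=np.full(geom.n_units, float(h_o)),
    )


def sample_gc_advance_rates(
    geom: GeneGeometry, q: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-site advance rates from local GC content.

    Each site draws N_GC ~ Binomial(50, 1/2) guanine/cytosine base pairs and
    advances at ``q_i = q * [0.5*N_GC + 1.5*(50 - N_GC)] / 50``: an all-GC
    site is twofold slower than an all-AT site, and the expectation is q.
    """
    if q <= 0:
        raise ValueError("q must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_gc = rng.binomial(SITE_BP, 0.5, size=geom.n_sites)
    return q * (0.5 * n_gc + 1.5 * (SITE_BP - n_gc)) / SITE_BP


def apply_static_defects(
    q_site: np.ndarray, regions: list[RegionAnnotation], factor: float = 0.5
) -> np.ndarray:
    """Multiply the advance rate by ``factor`` on every annotated site.

    Applied once, after GC sampling — the slowdown is in *addition* to the
    GC-content penalty, so the minimum reachable rate is 0.5 * 0.5q = 0.25q.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must lie in (0, 1]")
    _check_regions(regions, len(q_site))
    out = np.array(q_site, dtype=float, copy=True)
    for r in regions:
        out[r.site_range[0] - 1 : r.site_range[1]] *= factor
    return out


def sample_gc_nucleosome_rates(
    geom: GeneGeometry, h_c: float, h_o: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-nucleosome wrap/unwrap rates from the GC content of the wrapped 150 bp.

    A single N_GC ~ Binomial(150, 1/2) draw per nucleosome sets both rates:
    GC-rich nucleosomes wrap faster (h_c,m up to 1.25 h_c) and unwrap slower
    (h_o,m down to 0.75 h_o); expectations are h_c and h_o.
    """
    if h_c < 0 or h_o < 0:
        raise ValueError("h_c and h_o must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_bp = 3 * SITE_BP
    n_gc = rng.binomial(n_bp, 0.5, size=geom.n_units)
    h_c_m = h_c * (1.25 * n_gc + 0.75 * (n_bp - n_gc)) / n_bp
    h_o_m = h_o * (0.75 * n_gc + 1.25 * (n_bp - n_gc)) / n_bp
    return h_c_m, h_o_m


def apply_dynamic_defects(
    h_c_m: np.ndarray,
    h_o_m: np.ndarray,
    regions: list[RegionAnnotation],
    up_factor: float = 1.25,
    down_factor: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Stabilize annotated nucleosomes: wrap 25% faster, unwrap 25% slower.

    Applied once, multiplicatively, after GC sampling.
    """
    _check_regions(regions)
    hc = np.array(h_c_m, dtype=float, copy=True)
    ho = np.array(h_o_m, dtype=float, copy=True)
    for r in regions:
        for m in r.nucleosome_indices:
            hc[m - 1] *= up_factor
            ho[m - 1] *= down_factor
    return hc, ho


def default_annotated_gene(
    length_bp: int = 20_000, n_exons: int = 7
) -> tuple[GeneGeometry, list[RegionAnnotation]]:
    """The reference heterogeneous gene: a promoter CpG island plus evenly spaced exons.

    An 8-unit (1600 bp / 32 site) partially methylated CpG island sits at the
    promoter, followed by ``n_exons`` 2-unit (400 bp / 8 site) exon regions.
    The exon positions are placed with (near-)equal unit spacing between the
    island and the gene end; fair integer rounding distributes the remainder.
    """
    geom = build_uniform_gene(length_bp)
    cpg_units = 8
    exon_units = 2
    need = cpg_units + n_exons * exon_units
    if geom.n_units < need:
        raise ValueError(
            f"gene too short: {geom.n_units} units < {need} required for the annotations"
        )
    regions = [_region_from_units(geom, "cpg_island", 1, cpg_units)]
    remaining = geom.n_units - cpg_units
    slack = remaining - n_exons * exon_units
    cum = [round(slack * j / (n_exons + 1)) for j in range(n_exons + 2)]
    for j in range(1, n_exons + 1):
        start_unit = cpg_units + cum[j] + exon_units * (j - 1) + 1
        regions.append(_region_from_units(geom, "exon", start_unit, exon_units))
    _check_regions(regions, geom.n_sites)
    return geom, regions


def _region_from_units(
    geom: GeneGeometry, label: str, start_unit: int, n_units: int
) -> RegionAnnotation:
    units = geom.units[start_unit - 1 : start_unit - 1 + n_units]
    first = units[0].linker_sites[0]
    last = units[-1].nuc_sites[-1]
    return RegionAnnotation(
        label=label,
        site_range=(first, last),
        nucleosome_indices=tuple(u.index for u in units),
    )


# --- plain-text serialization -------------------------------------------


def geometry_table(
    geom: GeneGeometry, params: RateParams | None = None
) -> pd.DataFrame:
    """One row per site: 1-based label, owning unit, site class, advance rate."""
    nuc = geom.nuc_unit_of_site()
    unit = np.empty(geom.n_sites, dtype=int)
    for m, u in enumerate(geom.units):
        for s in (*u.linker_sites, *u.nuc_sites):
            unit[s - 1] = m + 1
    df = pd.DataFrame(
        {
            "site": np.arange(1, geom.n_sites + 1),
            "unit": unit,
            "site_class": np.where(nuc < 0, "linker", "nuc"),
        }
    )
    if params is not None:
        df["q_i"] = params.q_site
    return df


def rates_tables(
    geom: GeneGeometry,
    params: RateParams,
    regions: list[RegionAnnotation] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-site, per-nucleosome) tables that round-trip the parameter set."""
    sites = geometry_table(geom, params)
    annotated: dict[int, str] = {}
    for r in regions or []:
        for m in r.nucleosome_indices:
            annotated[m] = r.label
    nucs = pd.DataFrame(
        {
            "m": np.arange(1, geom.n_units + 1),
            "h_c_m": params.h_c_m,
            "h_o_m": params.h_o_m,
            "annotation": [annotated.get(m, "") for m in range(1, geom.n_units + 1)],
        }
    )
    return sites, nucs


def geometry_from_table(sites: pd.DataFrame, k_L: int, k_N: int) -> GeneGeometry:
    """Rebuild a :class:`GeneGeometry` from its per-site table."""
    n_sites = len(sites)
    units = []
    for m, grp in sites.groupby("unit", sort=True):
        linkers = tuple(int(s) for s in grp.loc[grp.site_class == "linker", "site"])
        nucs = tuple(int(s) for s in grp.loc[grp.site_class == "nuc", "site"])
        units.append(NucleosomeUnit(int(m), linkers, nucs))
    return GeneGeometry(n_sites=n_sites, units=tuple(units), k_L=k_L, k_N=k_N)
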