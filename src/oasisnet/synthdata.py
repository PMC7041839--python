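"""Synthetic field data: landscapes, pedigreed populations, genotypes, movement.

The generator emulates a radio-tracking study of Egyptian fruit bats at a
desert oasis: a few dozen tagged bats per season, nightly visits to a handful
of delineated fruit-tree foraging sites, diploid genotypes at 13 polymorphic
microsatellite loci, and an optional attraction toward kin already present at
a site.  It supplies ground truth (true visits, true pedigree relatedness) so
that downstream estimators can be tested by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SiteSpec",
    "RoostSpec",
    "Landscape",
    "Individual",
    "Pedigree",
    "SimConfig",
    "RegimeConfig",
    "simulate_pedigree",
    "relatedness_matrix",
    "simulate_genotypes",
    "random_allele_frequencies",
    "simulate_movement",
    "make_landscape",
    "default_config",
    "write_outputs",
    "landscape_from_geojson",
]

#: circle of this radius has the same area as a 100 x 100 m square site
SITE_RADIUS_M = 100.0 / math.sqrt(math.pi)


# ---------------------------------------------------------------------------
# landscape

@dataclass(frozen=True)
class SiteSpec:
    """One foraging site: a food patch of fruiting trees."""

    id: str
    x: float
    y: float
    radius: float = SITE_RADIUS_M
    #: season -> species -> count of trees with ripe fruit
    trees: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def availability(self, season: str) -> float:
        return float(sum(self.trees.get(season, {}).values()))


@dataclass(frozen=True)
class RoostSpec:
    id: str
    x: float
    y: float


@dataclass(frozen=True)
class Landscape:
    sites: tuple[SiteSpec, ...]
    roosts: tuple[RoostSpec, ...]
    #: (xmin, ymin, xmax, ymax) in metres
    extent: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sites]
        if len(ids) != len(set(ids)):
            raise ValueError("site ids must be unique")
        for s in self.sites:
            if s.radius <= 0:
                raise ValueError(f"site {s.id}: radius must be > 0")
            for season, counts in s.trees.items():
                if any(c < 0 for c in counts.values()):
                    raise ValueError(f"site {s.id}: negative tree count in {season}")
        xmin, ymin, xmax, ymax = self.extent
        for s in self.sites:
            if not (xmin <= s.x <= xmax and ymin <= s.y <= ymax):
                raise ValueError(f"site {s.id} outside extent")
        for r in self.roosts:
            if not (xmin <= r.x <= xmax and ymin <= r.y <= ymax):
                raise ValueError(f"roost {r.id} outside extent")

    def sites_for_season(self, season: str) -> list[SiteSpec]:
        """Sites with nonzero food availability in ``season``."""
        return [s for s in self.sites if s.availability(season) > 0]


# ---------------------------------------------------------------------------
# pedigree

@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "F" or "M"
    dam: str | None = None
    sire: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.dam is None and self.sire is None


@dataclass(frozen=True)
class Pedigree:
    """Individuals in topological order: parents precede offspring."""

    individuals: tuple[Individual, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if (ind.dam is None) != (ind.sire is None):
                raise ValueError(f"{ind.id}: non-founder needs both parents")
            if ind.dam is not None and (ind.dam not in seen or ind.sire not in seen):
                raise ValueError(f"{ind.id}: parents must precede offspring")
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id}")
            seen.add(ind.id)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def founder_count(self) -> int:
        return sum(ind.is_founder for ind in self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)


def simulate_pedigree(
    founders: int,
    generations: int,
    litter_rate: float = 2.0,
    rng: np.random.Generator | None = None,
) -> Pedigree:
    """Simulate a polygynous pedigree over discrete generations.

    Each female of the previous generation draws a sire uniformly from that
    generation's males and produces a Poisson(``litter_rate``) litter sired by
    him.  Full sibs share a litter, half sibs share only a sire, so all pair
    categories (parent-offspring, full-sib, half-sib, unrelated) arise for
    reasonable parameters.
    """
    if founders < 2:
        raise ValueError("insufficient founders")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(rng)
    inds: list[Individual] = []
    # alternate sexes so both are always present among founders
    prev = [
        Individual(id=f"G0_{i:03d}", sex="F" if i % 2 == 0 else "M")
        for i in range(founders)
    ]
    inds.extend(prev)
    counter = founders
    for g in range(1, generations + 1):
        females = [p for p in prev if p.sex == "F"]
        males = [p for p in prev if p.sex == "M"]
        if not females or not males:
            break
        cur: list[Individual] = []
        for dam in females:
            sire = males[rng.integers(len(males))]
            n_off = rng.poisson(litter_rate)
            for _ in range(n_off):
                sex = "F" if rng.random() < 0.5 else "M"
                cur.append(
                    Individual(
                        id=f"G{g}_{counter:03d}",
                        sex=sex,
                        dam=dam.id,
                        sire=sire.id,
                    )
                )
                counter += 1
        inds.extend(cur)
        prev = cur
    return Pedigree(tuple(inds))


def relatedness_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """True pairwise relatedness r = 2 * kinship, by recursive path counting.

    Founders are assumed unrelated and non-inbred.  The classic recursion on
    the tabular kinship coefficient f: f(i,i) = (1 + f(dam_i, sire_i)) / 2 and
    f(i,j) = (f(dam_i, j) + f(sire_i, j)) / 2 for i younger than j.
    """
    ids = pedigree.ids
    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    f = np.zeros((n, n))
    parents = [
        (
            index[ind.dam] if ind.dam is not None else -1,
            index[ind.sire] if ind.sire is not None else -1,
        )
        for ind in pedigree.individuals
    ]
    for i in range(n):
        d, s = parents[i]
        f[i, i] = 0.5 if d < 0 else 0.5 * (1.0 + f[d, s])
        for j in range(i):
            if d < 0:
                fij = 0.0  # founder, unrelated to anyone older
            else:
                fij = 0.5 * (f[d, j] + f[s, j])
            f[i, j] = f[j, i] = fij
    r = 2.0 * f
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# genotypes

def random_allele_frequencies(
    n_loci: int,
    rng: np.random.Generator | None = None,
    allele_range: tuple[int, int] = (3, 10),
) -> list[np.ndarray]:
    """Per-locus allele frequency vectors with Dirichlet(2) weights.

    Allele counts drawn uniformly from ``allele_range`` (inclusive), matching
    microsatellite panels where loci carry 3-10 alleles (mean about 6).
    """
    rng = np.random.default_rng(rng)
    lo, hi = allele_range
    freqs = []
    for _ in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        p = rng.dirichlet(np.full(k, 2.0))
        freqs.append(p)
    return freqs


def simulate_genotypes(
    pedigree: Pedigree,
    n_loci: int,
    allele_freqs: Sequence[np.ndarray],
    rng: np.random.Generator | None = None,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Drop genotypes through the pedigree.

    Founders draw both alleles from the locus frequencies; every non-founder
    inherits one allele from each parent, picked uniformly.  Returns a frame
    indexed by individual with columns ``L{l}_a`` / ``L{l}_b`` holding integer
    allele labels (missing cells are NaN).
    """
    if len(allele_freqs) != n_loci:
        raise ValueError("need one frequency vector per locus")
    for li, p in enumerate(allele_freqs):
        if abs(float(np.sum(p)) - 1.0) > 1e-9:
            raise ValueError(f"locus {li}: frequencies must sum to 1")
    rng = np.random.default_rng(rng)
    ids = pedigree.ids
    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    geno = np.zeros((n, n_loci, 2), dtype=int)
    for i, ind in enumerate(pedigree.individuals):
        for li, p in enumerate(allele_freqs):
            if ind.is_founder:
                geno[i, li] = rng.choice(len(p), size=2, p=p)
            else:
                d, s = index[ind.dam], index[ind.sire]
                geno[i, li, 0] = geno[d, li, rng.integers(2)]
                geno[i, li, 1] = geno[s, li, rng.integers(2)]
    cols: dict[str, np.ndarray] = {}
    for li in range(n_loci):
        cols[f"L{li + 1}_a"] = geno[:, li, 0]
        cols[f"L{li + 1}_b"] = geno[:, li, 1]
    gt = pd.DataFrame(cols, index=pd.Index(ids, name="individual"), dtype=float)
    if missing_rate > 0:
        mask = rng.random((n, n_loci)) < missing_rate
        for li in range(n_loci):
            gt.loc[mask[:, li], [f"L{li + 1}_a", f"L{li + 1}_b"]] = np.nan
    return gt


# ---------------------------------------------------------------------------
# movement

@dataclass(frozen=True)
class RegimeConfig:
    """Seasonal food regime: how many patches, how spread out, how rich."""

    n_sites: int
    #: per-site availability weights (tree counts); recycled if shorter
    availability: tuple[float, ...] = (10.0,)
    #: sites are scattered uniformly in a disc of this radius around the oasis
    dispersion_m: float = 2000.0


@dataclass(frozen=True)
class SimConfig:
    n_bats: int = 32
    n_nights: int = 8
    regimes: Mapping[str, RegimeConfig] = field(
        default_factory=lambda: dict(DEFAULT_REGIMES)
    )
    #: strength of attraction to kin already at a site (0 = none)
    kin_attraction: float = 0.0
    #: probability weight boost for previously used sites, in [0, 1]
    site_fidelity: float = 0.3
    availability_exponent: float = 1.0
    fix_noise_sd: float = 25.0
    fixes_per_visit: int = 5
    commute_fixes: int = 2
    n_loci: int = 13
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bats <= 0 or self.n_nights <= 0 or self.n_loci <= 0:
            raise ValueError("counts must be positive")
        if self.kin_attraction < 0:
            raise ValueError("kin_attraction must be >= 0")
        if not (0.0 <= self.site_fidelity <= 1.0):
            raise ValueError("site_fidelity must be in [0, 1]")


# Winter: many scattered patches (dates, mango, citrus, figs, jujube, guava,
# banana all fruiting); spring: food restricted to a couple of date patches
# close together.  Counts are qualitative: the contrast, not the magnitudes,
# is what the study design states.
DEFAULT_REGIMES: dict[str, RegimeConfig] = {
    "winter": RegimeConfig(n_sites=12, availability=(12, 8, 6, 10, 5, 7, 9, 6, 8, 5, 11, 7), dispersion_m=2000.0),
    "spring": RegimeConfig(n_sites=2, availability=(10, 8), dispersion_m=300.0),
    "summer": RegimeConfig(n_sites=12, availability=(14, 9, 8, 12, 6, 8, 10, 7, 9, 6, 12, 8), dispersion_m=2200.0),
}

_SPECIES = ("date", "fig", "mango", "citrus", "jujube", "guava", "banana")


def make_landscape(
    regimes: Mapping[str, RegimeConfig] | None = None,
    rng: np.random.Generator | None = None,
    n_roosts: int = 4,
) -> Landscape:
    """Lay out per-season foraging sites and day roosts around a central oasis."""
    regimes = dict(DEFAULT_REGIMES) if regimes is None else regimes
    rng = np.random.default_rng(rng)
    sites: list[SiteSpec] = []
    max_disp = max(rc.dispersion_m for rc in regimes.values())
    extent_half = max_disp + 500.0
    counter = 0
    for season, rc in regimes.items():
        if rc.n_sites <= 0:
            raise ValueError(f"regime {season}: empty site list")
        for k in range(rc.n_sites):
            # uniform in a disc of the regime's dispersion radius
            theta = rng.uniform(0, 2 * math.pi)
            rad = rc.dispersion_m * math.sqrt(rng.uniform(0.05, 1.0))
            avail = rc.availability[k % len(rc.availability)]
            species = _SPECIES[k % len(_SPECIES)] if season != "spring" else "date"
            sites.append(
                SiteSpec(
                    id=f"{season[:2].upper()}{counter:02d}",
                    x=rad * math.cos(theta),
                    y=rad * math.sin(theta),
                    trees={season: {species: int(avail)}},
                )
            )
            counter += 1
    roosts = tuple(
        RoostSpec(id=f"R{k}", x=float(rng.uniform(-400, 400)), y=float(rng.uniform(-400, 400)))
        for k in range(n_roosts)
    )
    return Landscape(
        sites=tuple(sites),
        roosts=roosts,
        extent=(-extent_half, -extent_half, extent_half, extent_half),
    )


def default_config(**overrides) -> SimConfig:
    return dataclasses.replace(SimConfig(), **overrides)


def _choose_sites(
    rng: np.random.Generator,
    site_ids: list[str],
    base_weight: np.ndarray,
    past_sites: set[str],
    occupancy: dict[str, list[str]],
    kin_row: Mapping[str, float],
    gamma: float,
    phi: float,
    n_pick: int,
) -> list[str]:
    """Sequential weighted sampling of distinct sites for one bat-night."""
    chosen: list[str] = []
    for _ in range(n_pick):
        avail_idx = [k for k, s in enumerate(site_ids) if s not in chosen]
        w = np.empty(len(avail_idx))
        for pos, k in enumerate(avail_idx):
            s = site_ids[k]
            wk = base_weight[k]
            if s in past_sites:
                # fidelity boost: phi=0 none, phi=1 five-fold preference
                wk *= 1.0 + 4.0 * phi
            occ = occupancy.get(s, [])
            if gamma > 0 and occ:
                mean_r = float(np.mean([kin_row[o] for o in occ]))
                wk *= math.exp(gamma * mean_r)
            w[pos] = wk
        w /= w.sum()
        chosen.append(site_ids[avail_idx[rng.choice(len(avail_idx), p=w)]])
    return chosen


def simulate_movement(
    landscape: Landscape,
    pedigree: Pedigree,
    config: SimConfig,
    season: str,
    rng: np.random.Generator | None = None,
    bat_ids: Sequence[str] | None = None,
    start_date: str = "2010-11-01",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate nightly foraging and emit telemetry fixes plus true visits.

    Each bat each night picks 1-3 distinct sites with probability proportional
    to availability**a x fidelity boost x exp(gamma * mean true relatedness to
    bats already assigned to the site that night).  Bats are assigned
    sequentially within a night (order reshuffled nightly) so kin attraction
    can reference earlier arrivals.  Fixes are Gaussian scatter around chosen
    site centres plus commuting fixes between roost and site.

    Returns ``(fixes, truth_visits)``; truth visits have integer night indices
    starting at 1, consistent with noon-to-noon night assignment of the fix
    timestamps.
    """
    if season not in config.regimes:
        raise ValueError(f"no regime configured for season {season!r}")
    sites = landscape.sites_for_season(season)
    if not sites:
        raise ValueError(f"empty site list for season {season!r}")
    rng = np.random.default_rng(rng)
    if bat_ids is None:
        ids = pedigree.ids
        if len(ids) < config.n_bats:
            raise ValueError("pedigree smaller than n_bats")
        bat_ids = list(rng.choice(ids, size=config.n_bats, replace=False))
    else:
        bat_ids = list(bat_ids)
    rel = relatedness_matrix(pedigree)
    site_ids = [s.id for s in sites]
    centers = {s.id: (s.x, s.y) for s in sites}
    base_w = np.array([s.availability(season) ** config.availability_exponent for s in sites])
    home_roost = {b: landscape.roosts[rng.integers(len(landscape.roosts))] for b in bat_ids}

    base = pd.Timestamp(start_date)
    fix_rows: list[tuple] = []
    visit_rows: list[tuple] = []
    past: dict[str, set[str]] = {b: set() for b in bat_ids}
    for night in range(1, config.n_nights + 1):
        occupancy: dict[str, list[str]] = {}
        order = list(rng.permutation(bat_ids))
        for bat in order:
            n_pick = int(rng.integers(1, min(3, len(site_ids)) + 1))
            kin_row = rel.loc[bat, :]
            chosen = _choose_sites(
                rng,
                site_ids,
                base_w,
                past[bat],
                occupancy,
                kin_row,
                config.kin_attraction,
                config.site_fidelity,
                n_pick,
            )
            roost = home_roost[bat]
            # night runs 20:00 -> 04:00; slot the visits in order
            t0 = base + pd.Timedelta(days=night - 1, hours=20)
            slot = pd.Timedelta(hours=8) / max(len(chosen), 1)
            for vi, sid in enumerate(chosen):
                occupancy.setdefault(sid, []).append(bat)
                past[bat].add(sid)
                visit_rows.append((bat, night, sid))
                cx, cy = centers[sid]
                tv = t0 + vi * slot
                for fi in range(config.fixes_per_visit):
                    ts = tv + pd.Timedelta(minutes=5 + 10 * fi)
                    fix_rows.append(
                        (
                            bat,
                            ts.isoformat(),
                            cx + rng.normal(0, config.fix_noise_sd),
                            cy + rng.normal(0, config.fix_noise_sd),
                            "triangulated",
                        )
                    )
                # commuting fixes along the roost-site leg (excluded from sites
                # by construction only when noise is small; that is fine)
                for ci in range(config.commute_fixes):
                    frac = rng.uniform(0.25, 0.75)
                    fix_rows.append(
                        (
                            bat,
                            (tv + pd.Timedelta(minutes=1 + ci)).isoformat(),
                            roost.x + frac * (cx - roost.x) + rng.normal(0, config.fix_noise_sd),
                            roost.y + frac * (cy - roost.y) + rng.normal(0, config.fix_noise_sd),
                            "triangulated",
                        )
                    )
    fixes = pd.DataFrame(fix_rows, columns=["bat_id", "timestamp", "x_m", "y_m", "source"])
    truth = pd.DataFrame(visit_rows, columns=["bat_id", "night", "site_id"]).drop_duplicates()
    return fixes, truth.reset_index(drop=True)


def simulate_roosting(
    landscape: Landscape,
    bat_ids: Sequence[str],
    n_days: int,
    rng: np.random.Generator | None = None,
    switch_prob: float = 0.2,
) -> pd.DataFrame:
    """Day-roost occupancy: each bat keeps a home roost, switching occasionally."""
    rng = np.random.default_rng(rng)
    roost_ids = [r.id for r in landscape.roosts]
    rows = []
    current = {b: roost_ids[rng.integers(len(roost_ids))] for b in bat_ids}
    for day in range(1, n_days + 1):
        for b in bat_ids:
            if rng.random() < switch_prob:
                current[b] = roost_ids[rng.integers(len(roost_ids))]
            rows.append((b, day, current[b]))
    return pd.DataFrame(rows, columns=["bat_id", "day", "roost_id"])


# ---------------------------------------------------------------------------
# output

def write_outputs(
    outdir: str | Path,
    landscape: Landscape,
    pedigree: Pedigree,
    genotypes: pd.DataFrame,
    fixes: pd.DataFrame,
    truth_visits: pd.DataFrame,
    config: SimConfig,
) -> None:
    """Write the simulated study to CSV/GeoJSON/YAML files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fixes = fixes.copy()
    fixes.to_csv(out / "fixes.csv", index=False)
    truth_visits.to_csv(out / "truth_visits.csv", index=False)
    genotypes.to_csv(out / "genotypes.csv")
    relatedness_matrix(pedigree).to_csv(out / "truth_kinship.csv")
    pd.DataFrame(
        [(r.id, r.x, r.y) for r in landscape.roosts], columns=["roost_id", "x_m", "y_m"]
    ).to_csv(out / "roosts.csv", index=False)
    features = []
    for s in landscape.sites:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
                "properties": {
                    "id": s.id,
                    "radius_m": s.radius,
                    "trees": {k: dict(v) for k, v in s.trees.items()},
                },
            }
        )
    (out / "sites.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    manifest = {"config": dataclasses.asdict(config), "seed": config.rng_seed}
    _write_manifest(out, manifest)


def _write_manifest(out: Path, manifest: dict) -> None:
    # RegimeConfig tuples -> lists for clean YAML
    for name, rc in manifest["config"]["regimes"].items():
        if dataclasses.is_dataclass(rc):
            manifest["config"]["regimes"][name] = dataclasses.asdict(rc)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def landscape_from_geojson(
    sites_path: str | Path, roosts_path: str | Path | None = None
) -> Landscape:
    """Load a landscape from the sites.geojson / roosts.csv pair.

    Point features become circular sites of the recorded radius (default: the
    100x100 m equivalent circle).  Works on files written by
    :func:`write_outputs` and on hand-prepared files of the same schema.
    """
    gj = json.loads(Path(sites_path).read_text())
    sites = []
    for feat in gj["features"]:
        x, y = feat["geometry"]["coordinates"]
        props = feat.get("properties", {})
        sites.append(
            SiteSpec(
                id=str(props["id"]),
                x=float(x),
                y=float(y),
                radius=float(props.get("radius_m", SITE_RADIUS_M)),
                trees={
                    season: {sp: int(c) for sp, c in counts.items()}
                    for season, counts in props.get("trees", {}).items()
                },
            )
        )
    roosts: tuple[RoostSpec, ...] = ()
    if roosts_path is not None:
        rt = pd.read_csv(roosts_path)
        roosts = tuple(
            RoostSpec(id=str(r.roost_id), x=float(r.x_m), y=float(r.y_m))
            for r in rt.itertuples()
        )
    xs = [s.x for s in sites] + [r.x for r in roosts]
    ys = [s.y for s in sites] + [r.y for r in roosts]
    pad = max((s.radius for s in sites), default=100.0)
    extent = (min(xs) - pad, min(ys) - pad, max(xs) + pad, max(ys) + pad)
    return Landscape(sites=tuple(sites), roosts=roosts, extent=extent)
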