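"""Synthetic multi-cohort microbiome data with known ground truth.

The generator emulates the statistical structure of multi-study fecal
metagenome collections used for colorectal-cancer marker discovery:

* compositional genus-level relative abundances (log-normal model, closed to
  sum 1 per sample);
* a shared "core" genus set detected in every cohort plus cohort-private
  genera;
* per-genus, per-cohort batch offsets so that study identity — not disease —
  dominates between-sample dissimilarity;
* planted marker genera whose log-abundance shifts with diagnostic group
  (healthy control HC, colorectal adenoma CA, carcinoma CRC), including
  "sharp" markers that are near-zero in HC/CA and strongly elevated in CRC;
* per-sample confounders (age, sex, BMI) that are distributionally associated
  with group but do not drive abundances;
* KEGG-ortholog (KO) functional tables whose linked features track a marker
  genus with a controlled rank correlation.

Every run returns a :class:`TruthRecord` naming the planted markers and links
so that recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .profiles import CohortProfile

GROUP_ORDER = ("HC", "CA", "CRC")


@dataclass(frozen=True)
class MarkerSpec:
    """One planted marker genus.

    ``shifts`` are mean log-abundance offsets added in (HC, CA, CRC) samples.
    ``sharp`` markers additionally get a low baseline so that they are rare
    outside CRC.
    """

    genus_index: int
    shifts: tuple[float, float, float]
    sharp: bool = False


@dataclass(frozen=True)
class KoLink:
    """A KO feature tied to a marker genus with signed rank-correlation
    strength in (-1, 1]."""

    ko_index: int
    genus_index: int
    strength: float


@dataclass
class SimulationConfig:
    n_cohorts: int = 6
    samples_per_group: dict = field(
        default_factory=lambda: {"HC": 30, "CA": 30, "CRC": 30}
    )
    n_genera: int = 130
    n_core_genera: int = 117
    markers: list[MarkerSpec] = field(default_factory=list)
    batch_sigma: float = 1.0  # sd of per-genus per-cohort log offsets
    noise_sigma: float = 1.0  # sd of per-sample log noise
    base_log_sigma: float = 2.0  # spread of genus baseline log abundances
    sharp_baseline: float = -3.0  # baseline log abundance of sharp markers
    # marker genera sit at the median baseline (sharp ones lower): CRC marker
    # taxa are low-to-moderate abundance, so their planted increase must not
    # compress the rest of the composition into spurious systematic shifts
    marker_baseline: float | None = 0.0
    n_ko: int = 200
    ko_links: list[KoLink] = field(default_factory=list)
    seed: int = 0

    def cohort_ids(self) -> list[str]:
        return [f"cohort{c + 1}" for c in range(self.n_cohorts)]

    def genus_names(self) -> list[str]:
        return [f"Genus{j:03d}" for j in range(self.n_genera)]

    def ko_names(self) -> list[str]:
        return [f"K{k + 1:05d}" for k in range(self.n_ko)]

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed must be set")
        for g, n in self.samples_per_group.items():
            if n < 2:
                raise ValueError(f"group {g}: need >=2 samples, got {n}")
        for m in self.markers:
            if not 0 <= m.genus_index < self.n_core_genera:
                raise ValueError(
                    f"marker genus index {m.genus_index} outside core range "
                    f"[0, {self.n_core_genera})"
                )
        for link in self.ko_links:
            if not 0 <= link.genus_index < self.n_genera:
                raise ValueError(f"ko link references absent genus {link.genus_index}")
            if not 0 <= link.ko_index < self.n_ko:
                raise ValueError(f"ko link references absent KO {link.ko_index}")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study preset: 6 cohorts, 30 samples per group, 12 planted
    CRC markers with 1.5-log-unit shifts, batch sigma 1.0.

    Markers mirror the structure reported for CRC gut metagenomes: three
    sharp genera (near-zero in HC, intermediate in CA, high in CRC — the
    Porphyromonas/Parvimonas/Peptostreptococcus pattern), three further
    CRC-enriched genera, and six CRC-depleted genera.
    """
    markers = (
        [MarkerSpec(j, (0.0, 0.5, 1.5), sharp=True) for j in range(3)]
        + [MarkerSpec(j, (0.0, 0.0, 1.5)) for j in range(3, 6)]
        + [MarkerSpec(j, (0.0, 0.0, -1.5)) for j in range(6, 12)]
    )
    # 4 linked KOs per marker, sign following the marker's CRC direction
    links = []
    k = 0
    for m in markers:
        sign = 1.0 if m.shifts[2] >= m.shifts[0] else -1.0
        for _ in range(4):
            links.append(KoLink(k, m.genus_index, sign * 0.8))
            k += 1
    cfg = SimulationConfig(markers=markers, ko_links=links, seed=seed)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


@dataclass
class TruthRecord:
    """Ground truth of one simulation: planted markers per contrast (with
    direction of change in CRC), batch offsets, and KO-genus links."""

    markers: dict  # contrast -> list of (genus_name, direction)
    sharp_markers: list
    cohort_offsets: dict  # cohort_id -> list of per-genus offsets
    ko_links: list  # (ko_name, genus_name, strength)

    def marker_names(self, contrast: str) -> list[str]:
        return [name for name, _ in self.markers[contrast]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _group_labels(samples_per_group: dict) -> list[str]:
    labels: list[str] = []
    for g in GROUP_ORDER:
        labels.extend([g] * samples_per_group.get(g, 0))
    for g in samples_per_group:
        if g not in GROUP_ORDER:
            labels.extend([g] * samples_per_group[g])
    return labels


def generate_cohorts(config: SimulationConfig) -> tuple[list[CohortProfile], TruthRecord]:
    """Draw the full multi-cohort dataset.

    Log abundance of genus j in sample i of cohort c:

        log x_ij = b_j + o_cj + delta_{g(i), j} + eps_ij

    with baseline b_j ~ N(0, base_log_sigma) shared across cohorts, batch
    offset o_cj ~ N(0, batch_sigma), group effect delta from the marker spec,
    and noise eps ~ N(0, noise_sigma).  Rows are exponentiated and closed to
    sum 1.  Cohort-private (non-core) genera are zeroed outside their own
    cohort.  Deterministic given ``config.seed``; each cohort consumes an
    independent RNG stream keyed by (seed, cohort index), so adding a cohort
    never perturbs earlier ones.
    """
    config.validate()
    genus_names = config.genus_names()
    rng_global = np.random.default_rng([config.seed, 1])
    base = rng_global.normal(0.0, config.base_log_sigma, size=config.n_genera)
    shift_by_group: dict[str, np.ndarray] = {
        g: np.zeros(config.n_genera) for g in GROUP_ORDER
    }
    for m in config.markers:
        if m.sharp:
            base[m.genus_index] = config.sharp_baseline
        elif config.marker_baseline is not None:
            base[m.genus_index] = config.marker_baseline
        for g, s in zip(GROUP_ORDER, m.shifts):
            shift_by_group[g][m.genus_index] = s

    profiles: list[CohortProfile] = []
    offsets: dict[str, list[float]] = {}
    for c, cohort_id in enumerate(config.cohort_ids()):
        rng = np.random.default_rng([config.seed, 0, c])
        o = rng.normal(0.0, config.batch_sigma, size=config.n_genera)
        offsets[cohort_id] = [round(float(v), 6) for v in o]
        labels = _group_labels(config.samples_per_group)
        n = len(labels)
        loglik = base[None, :] + o[None, :]
        delta = np.stack(
            [shift_by_group.get(g, np.zeros(config.n_genera)) for g in labels]
        )
        eps = rng.normal(0.0, config.noise_sigma, size=(n, config.n_genera))
        x = np.exp(loglik + delta + eps)
        # cohort-private genera: genus j >= n_core belongs to cohort
        # (j - n_core) mod n_cohorts only
        for j in range(config.n_core_genera, config.n_genera):
            if (j - config.n_core_genera) % config.n_cohorts != c:
                x[:, j] = 0.0
        x /= x.sum(axis=1, keepdims=True)
        sample_ids = [f"{cohort_id}_S{i:03d}" for i in range(n)]
        ab = pd.DataFrame(x, index=sample_ids, columns=genus_names)
        md = _metadata(rng, sample_ids, labels)
        profiles.append(CohortProfile(cohort_id, ab, md))

    truth = TruthRecord(
        markers={
            "CRC_vs_HC": [
                (genus_names[m.genus_index], "up" if m.shifts[2] > m.shifts[0] else "down")
                for m in config.markers
                if m.shifts[2] != m.shifts[0]
            ],
            "CRC_vs_CA": [
                (genus_names[m.genus_index], "up" if m.shifts[2] > m.shifts[1] else "down")
                for m in config.markers
                if m.shifts[2] != m.shifts[1]
            ],
        },
        sharp_markers=[genus_names[m.genus_index] for m in config.markers if m.sharp],
        cohort_offsets=offsets,
        ko_links=[
            (config.ko_names()[l.ko_index], genus_names[l.genus_index], l.strength)
            for l in config.ko_links
        ],
    )
    return profiles, truth


def _metadata(rng: np.random.Generator, sample_ids, labels) -> pd.DataFrame:
    """Confounders distributionally shifted by group but causally inert."""
    age_mu = {"HC": 58.0, "CA": 62.0, "CRC": 65.0}
    rows = []
    for g in labels:
        age = float(np.clip(rng.normal(age_mu.get(g, 55.0), 10.0), 25, 90))
        sex = "F" if rng.random() < 0.5 else "M"
        bmi = float(np.clip(rng.normal(24.5, 3.5), 16, 42))
        stage = rng.choice(["I", "II", "III", "IV"]) if g == "CRC" else ""
        rows.append({"group": g, "age": round(age, 1), "sex": sex,
                     "bmi": round(bmi, 1), "stage": stage})
    return pd.DataFrame(rows, index=sample_ids)


def generate_ko_table(
    profiles: list[CohortProfile],
    truth: TruthRecord,
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """KO relative-abundance tables (samples x KO) per cohort.

    A linked KO's log abundance is ``s * z_genus + sqrt(1 - s^2) * noise``
    around a KO-specific baseline, where ``z_genus`` is the within-cohort
    standardized log abundance of the linked genus — a monotone coupling, so
    strength 1 yields Spearman rho exactly 1.  Unlinked KOs are independent
    log-normal.  Rows are NOT closed, so planted monotone links survive
    exactly; normalize downstream if fractions are required.
    """
    config.validate()
    ko_names = config.ko_names()
    rng_global = np.random.default_rng([config.seed, 3])
    mu = rng_global.normal(0.0, 1.0, size=config.n_ko)
    linked = {l.ko_index: l for l in config.ko_links}
    out: dict[str, pd.DataFrame] = {}
    for c, p in enumerate(profiles):
        rng = np.random.default_rng([config.seed, 2, c])
        n = p.n_samples
        z = rng.normal(0.0, 1.0, size=(n, config.n_ko))
        logko = mu[None, :] + z
        vals = p.values()
        for k, link in linked.items():
            g = np.log(vals[:, link.genus_index] + 1e-12)
            sd = g.std()
            zg = (g - g.mean()) / (sd if sd > 0 else 1.0)
            s = link.strength
            logko[:, k] = mu[k] + s * zg + np.sqrt(max(0.0, 1.0 - s * s)) * z[:, k]
        x = np.exp(logko)
        out[p.cohort_id] = pd.DataFrame(x, index=p.sample_ids, columns=ko_names)
    return out
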