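"""Synthetic cohorts for normative dysconnectivity analysis.

Generates a healthy reference cohort and a patient cohort measured at two
sessions (baseline, 6-month follow-up), with dysconnectivity planted on known
connections so that every downstream stage — connectivity, deviation scoring,
mixed models, clinical regressions and imaging transcriptomics — can be tested
against ground truth without any external data.

The generative model is deliberately simple: BOLD-like series are stationary
Gaussian with a prescribed region-by-region correlation matrix, so the
population connectivity of every cohort is known in closed form. Planted
effects shift the Fisher-z connectivity of selected connections at baseline
and attenuate by a known fraction at follow-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SESSIONS = ("baseline", "followup")

#: Canonical resting-state networks assessed by the specific DCI.
NETWORKS = (
    "visual",
    "somatomotor",
    "limbic",
    "frontoparietal",
    "default-mode",
    "dorsal-attention",
    "salience",
    "subcortical",
)

#: Additional anatomical seed groups used for region-pair DCIs.
REGION_GROUPS = (
    "hippocampal-formation",
    "prefrontal",
    "thalamus",
    "middle-frontal",
)

CLINICAL_SCORES = ("GAF", "PANSS", "cognition")


# ---------------------------------------------------------------------------
# specs


@dataclass
class CohortSpec:
    """Dimensions and population structure of a synthetic study.

    ``region_meta`` carries one row per region (both hemispheres) with columns
    ``region_id, hemisphere, network, x, y, z, parcel_id``; ``base_covariance``
    maps hemisphere -> correlation matrix in the hemisphere's region order.

    ``subject_dof`` controls between-subject connectome heterogeneity: each
    subject's population correlation matrix is the correlation of a Wishart
    draw from the base covariance with this many degrees of freedom (always
    positive definite; per-connection Fisher-z spread ~ 1/sqrt(dof - 3),
    stable within subject across sessions). ``None`` gives every subject the
    base covariance exactly.
    """

    n_reference: int
    n_patients: int
    n_timepoints: int
    tr_seconds: float
    region_meta: pd.DataFrame
    base_covariance: dict[str, np.ndarray]
    noise_sd: float = 0.0
    ar1: float = 0.0
    subject_scale_range: tuple[float, float] = (0.5, 1.5)
    subject_dof: int | None = 100

    def regions(self, hemisphere: str) -> list[str]:
        m = self.region_meta
        return list(m.loc[m["hemisphere"] == hemisphere, "region_id"])

    @property
    def n_regions_left(self) -> int:
        return len(self.regions("L"))

    @property
    def n_regions_right(self) -> int:
        return len(self.regions("R"))

    def validate(self) -> None:
        if self.n_regions_left + self.n_regions_right < 20:
            raise ValueError("need at least 20 regions in total")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")
        if self.subject_dof is not None and self.subject_dof <= max(
            len(self.regions("L")), len(self.regions("R"))
        ):
            raise ValueError("subject_dof must exceed the hemisphere region count")
        if set(self.region_meta["hemisphere"]) - {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        known = set(NETWORKS) | set(REGION_GROUPS)
        unknown = set(self.region_meta["network"]) - known
        if unknown:
            raise ValueError(f"unknown network labels: {sorted(unknown)}")
        for hemi in ("L", "R"):
            c = self.base_covariance[hemi]
            n = len(self.regions(hemi))
            if c.shape != (n, n):
                raise ValueError(f"base_covariance[{hemi}] shape mismatch")
            if not np.allclose(c, c.T):
                raise ValueError(f"base_covariance[{hemi}] not symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError(f"base_covariance[{hemi}] diagonal must be 1")


@dataclass
class PlantedEffect:
    """Ground-truth dysconnectivity planted on a set of connections.

    ``target`` is either a network name (all within-network, within-hemisphere
    pairs) or an explicit list of ``(region_id, region_id)`` pairs.
    ``baseline_shift`` is the magnitude of the Fisher-z shift at baseline;
    at follow-up the shift is multiplied by ``1 - attenuation``.
    """

    target: str | list[tuple[str, str]]
    baseline_shift: float
    attenuation: float
    direction: str = "hyper"

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.baseline_shift < 0:
            raise ValueError("baseline_shift is a magnitude; use direction='hypo'")

    @property
    def signed_shift(self) -> float:
        return self.baseline_shift if self.direction == "hyper" else -self.baseline_shift

    def resolve_pairs(self, region_meta: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
        """Connection index pairs per hemisphere (hemisphere-local indices)."""
        out: dict[str, list[tuple[int, int]]] = {"L": [], "R": []}
        for hemi in ("L", "R"):
            rows = region_meta[region_meta["hemisphere"] == hemi].reset_index(drop=True)
            index = {rid: i for i, rid in enumerate(rows["region_id"])}
            if isinstance(self.target, str):
                members = [index[r] for r in rows.loc[rows["network"] == self.target, "region_id"]]
                out[hemi] = [(a, b) for k, a in enumerate(members) for b in members[k + 1:]]
            else:
                for ra, rb in self.target:
                    if (ra in index) != (rb in index):
                        raise ValueError(f"pair ({ra}, {rb}) crosses hemispheres")
                    if ra in index:
                        out[hemi].append((index[ra], index[rb]))
        if isinstance(self.target, str) and not (out["L"] or out["R"]):
            raise ValueError(f"target network {self.target!r} has no connections")
        return out


@dataclass
class ExpressionSpec:
    """Parcel-by-gene expression with one gene set spatially coupled to a map."""

    n_genes: int
    gene_sets: dict[str, list[str]]
    planted_set: str
    coupling: float
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.planted_set not in self.gene_sets:
            raise ValueError(f"planted_set {self.planted_set!r} not among gene sets")
        if any(len(g) == 0 for g in self.gene_sets.values()):
            raise ValueError("every gene set must be non-empty")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticStudy:
    """A generated study: series, covariates and the planted ground truth.

    ``true_region_change`` holds, per patient and region, the true reduction in
    Fisher-z deviation from baseline to follow-up summed over the region's
    planted connections (positive = dysconnectivity reduced); it is the ground
    truth that clinical couplings and recovery tests are written against.
    """

    spec: CohortSpec
    effects: list[PlantedEffect]
    reference_timeseries: list[pd.DataFrame]
    patient_timeseries: dict[tuple[str, str], pd.DataFrame]
    covariates: pd.DataFrame
    subject_scale: pd.Series
    true_region_change: pd.DataFrame
    true_network_change: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return list(self.covariates["subject"])


# ---------------------------------------------------------------------------
# default spec construction


#: approximate share of each canonical network in one hemisphere, patterned
#: on the unequal surface fractions of standard 7-network cortical atlases
#: (default-mode largest, limbic smallest) plus a small subcortical share
NETWORK_PROPORTIONS = {
    "visual": 0.13,
    "somatomotor": 0.155,
    "limbic": 0.065,
    "frontoparietal": 0.135,
    "default-mode": 0.21,
    "dorsal-attention": 0.11,
    "salience": 0.11,
    "subcortical": 0.085,
}


def _allocate_regions(n: int) -> list[str]:
    """Assign ``n`` regions of one hemisphere to networks and seed groups.

    The four anatomical seed groups get a small fixed share; the remaining
    regions are split across the eight networks by ``NETWORK_PROPORTIONS``
    (largest-remainder rounding, at least one region per network).
    """
    if n < 24:
        raise ValueError("need at least 24 regions per hemisphere")
    # every network and anatomical group needs >= 2 regions so that each
    # within-set scope has at least one connection
    per_group = max(2, round(n / 20))
    n_net = n - per_group * len(REGION_GROUPS)
    weights = np.array([NETWORK_PROPORTIONS[net] for net in NETWORKS])
    ideal = weights / weights.sum() * (n_net - 2 * len(NETWORKS))
    counts = 2 + np.floor(ideal).astype(int)
    for k in np.argsort(-(ideal - np.floor(ideal))):
        if counts.sum() >= n_net:
            break
        counts[k] += 1
    labels: list[str] = []
    for net, c in zip(NETWORKS, counts):
        labels += [net] * int(c)
    for grp in REGION_GROUPS:
        labels += [grp] * per_group
    return labels


def _region_meta(n_per_hemisphere: int) -> pd.DataFrame:
    """Deterministic region table: clustered coordinates, 1:1 parcels."""
    groups = list(NETWORKS) + list(REGION_GROUPS)
    rows = []
    for hemi, xsign in (("L", -1.0), ("R", 1.0)):
        labels = _allocate_regions(n_per_hemisphere)
        counter: dict[str, int] = {}
        for i, net in enumerate(labels):
            j = counter.get(net, 0)
            counter[net] = j + 1
            g = groups.index(net)
            cx, cy, cz = xsign * 25.0, 16.0 * (g % 4), 16.0 * (g // 4)
            ox, oy, oz = 4.0 * (j % 2), 4.0 * ((j // 2) % 2), 4.0 * (j // 4)
            rows.append(
                {
                    "region_id": f"{hemi}{i:03d}",
                    "hemisphere": hemi,
                    "network": net,
                    "x": cx + xsign * ox,
                    "y": cy + oy,
                    "z": cz + oz,
                    "parcel_id": f"P-{hemi}{i:03d}",
                }
            )
    return pd.DataFrame(rows)


def _block_covariance(labels: list[str], r_within: float, r_between: float) -> np.ndarray:
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    c = np.where(same, r_within, r_between).astype(float)
    np.fill_diagonal(c, 1.0)
    return c


def default_cohort_spec(
    n_reference: int = 40,
    n_patients: int = 12,
    n_regions_per_hemisphere: int = 60,
    n_timepoints: int = 300,
    tr_seconds: float = 2.0,
    r_within: float = 0.3,
    r_between: float = 0.05,
    **kwargs,
) -> CohortSpec:
    """Desk-scale study: 40 reference subjects, 12 patients, 60 regions/hemisphere."""
    meta = _region_meta(n_regions_per_hemisphere)
    cov = {
        hemi: _block_covariance(
            list(meta.loc[meta["hemisphere"] == hemi, "network"]), r_within, r_between
        )
        for hemi in ("L", "R")
    }
    spec = CohortSpec(
        n_reference=n_reference,
        n_patients=n_patients,
        n_timepoints=n_timepoints,
        tr_seconds=tr_seconds,
        region_meta=meta,
        base_covariance=cov,
        **kwargs,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# covariance machinery


def nearest_positive_definite(a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped PD repair, rescaled back to unit diagonal."""
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    repaired = (v * np.clip(w, eps, None)) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def _shifted_covariance(base: np.ndarray, zshift: np.ndarray) -> np.ndarray:
    """Apply a Fisher-z shift matrix to a correlation matrix.

    Shifts act on the arctanh scale and are mapped back through tanh, which
    keeps every off-diagonal inside (-1, 1) by construction.
    """
    off = ~np.eye(base.shape[0], dtype=bool)
    if np.any(np.abs(base[off]) >= 1.0):
        raise ValueError("base correlations must lie strictly inside (-1, 1)")
    z = np.arctanh(base * off)
    c = np.tanh(z + zshift * off)
    np.fill_diagonal(c, 1.0)
    eigmin = np.linalg.eigvalsh(c).min()
    if eigmin <= 1e-10:
        logger.warning(
            "shifted covariance lost positive definiteness (min eigenvalue %.3g); "
            "applying nearest-PD repair",
            eigmin,
        )
        c = nearest_positive_definite(c)
    return c


def _shift_matrices(
    spec: CohortSpec, effects: list[PlantedEffect]
) -> dict[str, dict[str, np.ndarray]]:
    """Per session, per hemisphere: summed signed Fisher-z shift matrix."""
    out = {
        ses: {h: np.zeros_like(spec.base_covariance[h]) for h in ("L", "R")}
        for ses in SESSIONS
    }
    for eff in effects:
        pairs = eff.resolve_pairs(spec.region_meta)
        for hemi in ("L", "R"):
            for i, j in pairs[hemi]:
                out["baseline"][hemi][i, j] += eff.signed_shift
                out["baseline"][hemi][j, i] += eff.signed_shift
                f = eff.signed_shift * (1.0 - eff.attenuation)
                out["followup"][hemi][i, j] += f
                out["followup"][hemi][j, i] += f
    return out


def _simulate_series(
    cov: np.ndarray, n_timepoints: int, rng: np.random.Generator, ar1: float, noise_sd: float
) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    eps = rng.standard_normal((n_timepoints, cov.shape[0])) @ chol.T
    if ar1 > 0:
        x = np.empty_like(eps)
        scale = np.sqrt(1.0 - ar1**2)
        x[0] = eps[0]
        for t in range(1, n_timepoints):
            x[t] = ar1 * x[t - 1] + scale * eps[t]
    else:
        x = eps
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


# ---------------------------------------------------------------------------
# generators


def _subject_population_cov(
    base: np.ndarray, rng: np.random.Generator, dof: int | None
) -> np.ndarray:
    """One subject's own population correlation matrix around the base."""
    if dof is None:
        return base
    w = rng.standard_normal((dof, base.shape[0])) @ np.linalg.cholesky(base).T
    return np.corrcoef(w, rowvar=False)


def generate_cohort(
    spec: CohortSpec, effects: list[PlantedEffect], seed: int
) -> SyntheticStudy:
    """Draw the reference cohort and the two-session patient cohort.

    Every subject first receives an individual population correlation matrix
    around the base covariance (see ``CohortSpec.subject_dof``), constant
    across that subject's sessions. Each patient's baseline matrix then
    carries the planted Fisher-z shifts scaled by a per-subject
    susceptibility factor; at follow-up each effect's shift is multiplied by
    ``1 - attenuation``. Identical inputs yield bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    hemis = ("L", "R")
    region_ids = {h: spec.regions(h) for h in hemis}

    def draw_subject(covs: dict[str, np.ndarray]) -> pd.DataFrame:
        cols = {}
        for h in hemis:
            x = _simulate_series(covs[h], spec.n_timepoints, rng, spec.ar1, spec.noise_sd)
            for k, rid in enumerate(region_ids[h]):
                cols[rid] = x[:, k]
        return pd.DataFrame(cols)

    base_covs = {h: spec.base_covariance[h] for h in hemis}
    reference = [
        draw_subject(
            {h: _subject_population_cov(base_covs[h], rng, spec.subject_dof) for h in hemis}
        )
        for _ in range(spec.n_reference)
    ]

    shifts = _shift_matrices(spec, effects)
    subjects = [f"sub-{i + 1:02d}" for i in range(spec.n_patients)]
    lo, hi = spec.subject_scale_range
    scale = pd.Series(rng.uniform(lo, hi, size=spec.n_patients), index=subjects, name="scale")

    patient_ts: dict[tuple[str, str], pd.DataFrame] = {}
    for sub in subjects:
        own = {h: _subject_population_cov(base_covs[h], rng, spec.subject_dof) for h in hemis}
        for ses in SESSIONS:
            covs = {
                h: _shifted_covariance(own[h], scale[sub] * shifts[ses][h])
                for h in hemis
            }
            patient_ts[(sub, ses)] = draw_subject(covs)

    covariates = pd.DataFrame(
        {
            "subject": subjects,
            "age": np.round(rng.normal(35.0, 8.0, spec.n_patients)).clip(18, 65),
            "sex": rng.choice(["F", "M"], spec.n_patients),
            "cpz": np.abs(rng.normal(400.0, 150.0, spec.n_patients)).round(1),
            "trainings": rng.integers(20, 60, spec.n_patients),
            "group": np.where(np.arange(spec.n_patients) % 2 == 0, "AET", "FSBT"),
        }
    )

    # ground truth: per-region reduction of planted Fisher-z deviation
    all_ids = list(spec.region_meta["region_id"])
    truth = pd.DataFrame(0.0, index=subjects, columns=all_ids)
    for eff in effects:
        pairs = eff.resolve_pairs(spec.region_meta)
        for hemi in hemis:
            ids = region_ids[hemi]
            for i, j in pairs[hemi]:
                red = eff.baseline_shift * eff.attenuation
                truth[ids[i]] += red * scale.values
                truth[ids[j]] += red * scale.values
    net_of = dict(zip(spec.region_meta["region_id"], spec.region_meta["network"]))
    net_truth = truth.T.groupby(truth.columns.map(net_of)).mean().T

    return SyntheticStudy(
        spec=spec,
        effects=list(effects),
        reference_timeseries=reference,
        patient_timeseries=patient_ts,
        covariates=covariates,
        subject_scale=scale,
        true_region_change=truth,
        true_network_change=net_truth,
    )


def default_gene_sets(genes_per_set: int = 40) -> dict[str, list[str]]:
    """Synthetic cell-type gene sets (Ex, In, Ast, Oli, OPC, Mic, End, Per)."""
    cell_types = ["Ex", "In", "Ast", "Oli", "OPC", "Mic", "End", "Per"]
    return {
        ct: [f"{ct.upper()}_{i + 1:03d}" for i in range(genes_per_set)] for ct in cell_types
    }


def generate_expression(
    spec: ExpressionSpec, target_map: pd.Series, seed: int
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Parcel-by-gene expression with the planted set coupled to ``target_map``.

    Planted genes are ``coupling * standardised(target_map) + noise_sd * eps``;
    all other genes are pure noise with the same noise scale.
    """
    spec.validate()
    if len(target_map) < 20:
        raise ValueError("target_map must cover at least 20 parcels")
    rng = np.random.default_rng(seed)
    set_genes = sorted({g for gs in spec.gene_sets.values() for g in gs})
    if len(set_genes) > spec.n_genes:
        raise ValueError("n_genes smaller than the union of gene sets")
    filler = [f"G{i + 1:05d}" for i in range(spec.n_genes - len(set_genes))]
    genes = set_genes + filler
    planted = set(spec.gene_sets[spec.planted_set])

    values = np.asarray(target_map, dtype=float)
    z = (values - values.mean()) / values.std()
    expr = spec.noise_sd * rng.standard_normal((len(target_map), len(genes)))
    for k, g in enumerate(genes):
        if g in planted:
            expr[:, k] += spec.coupling * z
    return pd.DataFrame(expr, index=target_map.index, columns=genes), dict(spec.gene_sets)


def generate_clinical(
    study: SyntheticStudy,
    coupling: dict[str, tuple[str, float]],
    seed: int,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Clinical change scores coupled to true network deviation changes.

    ``coupling`` maps network name -> (score name, strength). Each subject's
    change score is the strength-weighted sum of that subject's true deviation
    reductions in the coupled networks, plus Gaussian noise. All three change
    scores follow the convention positive = improvement.
    """
    for net, (score, _strength) in coupling.items():
        if score not in CLINICAL_SCORES:
            raise ValueError(f"unknown clinical score {score!r}; expected {CLINICAL_SCORES}")
        if net not in study.true_network_change.columns:
            raise ValueError(f"unknown network {net!r}")
    rng = np.random.default_rng(seed)
    subjects = study.subjects
    out = pd.DataFrame({"subject": subjects})
    for score in CLINICAL_SCORES:
        signal = np.zeros(len(subjects))
        for net, (sc, strength) in coupling.items():
            if sc == score:
                signal = signal + strength * study.true_network_change[net].values
        out[score] = signal + noise_sd * rng.standard_normal(len(subjects))
    return out
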