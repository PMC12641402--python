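"""Dysconnectivity index (DCI): normative deviation scoring of connectivity.

A healthy reference cohort defines, for every within-hemisphere connection,
the normal range of Fisher-z connectivity (per-connection mean mu and SD
sigma). A connection of a given subject is *dysconnected* when its Fisher-z
value deviates from the reference mean by more than ``threshold_k`` reference
SDs (two-sided). Counting, per region, the incident dysconnected connections
gives the dysconnectivity count (DCC); summing DCC over a hemisphere (or a
seed set of regions) and dividing by the number of regions gives the
(specific) DCI.

Longitudinal change maps standardise each region's DCC across all
participants (both sessions pooled) and take baseline minus follow-up, so a
positive change means dysconnectivity was reduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

SD_FLOOR = 1e-6


@dataclass
class ReferenceNorm:
    """Per-connection normal range of Fisher-z connectivity, one hemisphere.

    ``calibration`` selects how the deviation threshold treats the sampling
    uncertainty of the fitted mean and SD:

    * ``"predictive"`` (default) — flag when the predictive t-score
      ``|z - mu| / (sigma * sqrt(1 + 1/n))`` exceeds the t(n-1) quantile
      matching a Gaussian k-SD tail, so a healthy held-out subject is flagged
      on exactly a 2*Phi(-k) fraction of connections at any reference size.
    * ``"plugin"`` — the naive rule ``|z - mu| > k * sigma``, which over-flags
      for finite reference cohorts (the two coincide as n grows).
    """

    hemisphere: str
    mu: np.ndarray
    sigma: np.ndarray
    region_ids: list[str]
    threshold_k: float = 2.0
    sd_floor: float = SD_FLOOR
    n_reference: int = 0
    calibration: str = "predictive"

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if self.mu.shape != (n, n) or self.sigma.shape != (n, n):
            raise ValueError("mu/sigma shape must match region_ids")
        if (self.sigma < self.sd_floor).any():
            raise ValueError("sigma below sd_floor; fit via fit_reference_norm")
        if self.calibration not in ("predictive", "plugin"):
            raise ValueError("calibration must be 'predictive' or 'plugin'")

    @property
    def k_effective(self) -> float:
        """Multiplier of sigma actually used by the deviation rule."""
        if self.calibration == "plugin" or self.n_reference < 2:
            return self.threshold_k
        from scipy import stats as sps

        tail = sps.norm.sf(self.threshold_k)
        return float(
            sps.t.isf(tail, self.n_reference - 1)
            * np.sqrt(1.0 + 1.0 / self.n_reference)
        )


@dataclass
class DCCMap:
    """Per-region count of incident dysconnected connections (one hemisphere)."""

    subject_id: str
    session: str
    hemisphere: str
    dcc: pd.Series


@dataclass
class DCISummary:
    subject_id: str
    session: str
    scope: str
    hemisphere: str
    dci: float


@dataclass
class SeedDefinition:
    """A scope for the specific DCI: connections with one end in A, other in B.

    ``region_set_b`` equal to ``region_set_a`` (or None) gives a within-set
    scope such as a single network or the hippocampal formation.
    """

    name: str
    region_set_a: list[str]
    region_set_b: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.region_set_a:
            raise ValueError("region_set_a must be non-empty")
        if self.region_set_b is None:
            self.region_set_b = list(self.region_set_a)


@dataclass
class ChangeMap:
    """Per-region standardised DCC change; positive = reduction."""

    subject_id: str
    delta_dcc: pd.Series
    convention: str = "positive = reduction in dysconnectivity"


# ---------------------------------------------------------------------------


def fit_reference_norm(
    ref_mats: list[ConnectivityMatrix],
    threshold_k: float = 2.0,
    sd_floor: float = SD_FLOOR,
    calibration: str = "predictive",
) -> ReferenceNorm:
    """Per-connection mean and sample SD of Fisher-z across reference subjects.

    All matrices must share hemisphere and region order; SDs below
    ``sd_floor`` are floored so the deviation rule is always defined.
    """
    if len(ref_mats) < 10:
        raise ValueError("need at least 10 reference subjects")
    first = ref_mats[0]
    for m in ref_mats[1:]:
        if m.hemisphere != first.hemisphere or m.region_ids != first.region_ids:
            bad = [m.subject_id for m in ref_mats
                   if m.hemisphere != first.hemisphere or m.region_ids != first.region_ids]
            raise ValueError(f"mismatched hemisphere/region order for subjects: {bad}")
    stack = np.stack([m.z for m in ref_mats])
    mu = stack.mean(axis=0)
    sigma = np.maximum(stack.std(axis=0, ddof=1), sd_floor)
    return ReferenceNorm(
        hemisphere=first.hemisphere,
        mu=mu,
        sigma=sigma,
        region_ids=list(first.region_ids),
        threshold_k=threshold_k,
        sd_floor=sd_floor,
        n_reference=len(ref_mats),
        calibration=calibration,
    )


def dysconnection_mask(mat: ConnectivityMatrix, norm: ReferenceNorm) -> np.ndarray:
    """Binary symmetric deviation flags: |z - mu| > k_effective * sigma.

    ``k_effective`` is the norm's calibrated threshold multiplier (see
    ``ReferenceNorm.calibration``); with plug-in calibration it is exactly
    ``threshold_k``.
    """
    if mat.hemisphere != norm.hemisphere or mat.region_ids != norm.region_ids:
        raise ValueError("matrix and norm must share hemisphere and region order")
    mask = np.abs(mat.z - norm.mu) > norm.k_effective * norm.sigma
    np.fill_diagonal(mask, False)
    return mask


def dcc_map(mask: np.ndarray, region_ids: list[str],
            subject_id: str = "", session: str = "", hemisphere: str = "") -> DCCMap:
    """Per-region incident count of flagged connections (row sums)."""
    mask = np.asarray(mask, dtype=bool)
    if not np.array_equal(mask, mask.T):
        raise ValueError("dysconnection mask must be symmetric")
    counts = pd.Series(mask.sum(axis=1).astype(int), index=region_ids, name="dcc")
    return DCCMap(subject_id=subject_id, session=session, hemisphere=hemisphere, dcc=counts)


def whole_brain_dci(dcc: DCCMap, n_regions: int | None = None) -> DCISummary:
    """Hemisphere DCI: total DCC normalised by the hemisphere's region count."""
    n = len(dcc.dcc) if n_regions is None else n_regions
    if n != len(dcc.dcc):
        raise ValueError("n_regions does not match the DCC map")
    return DCISummary(
        subject_id=dcc.subject_id,
        session=dcc.session,
        scope="whole_brain",
        hemisphere=dcc.hemisphere,
        dci=float(dcc.dcc.sum()) / n,
    )


def specific_dci(
    mat: ConnectivityMatrix, seed: SeedDefinition, norm: ReferenceNorm
) -> DCISummary:
    """DCI restricted to connections with one end in set A and the other in B.

    The DCC and the region-count normaliser are computed over the seed's own
    regions only (the union of A and B within this hemisphere).
    """
    ids = mat.region_ids
    index = {r: i for i, r in enumerate(ids)}
    a = [index[r] for r in seed.region_set_a if r in index]
    b = [index[r] for r in seed.region_set_b if r in index]
    if not a or not b:
        raise ValueError(f"seed {seed.name!r}: no regions in hemisphere {mat.hemisphere}")
    keep = np.zeros_like(mat.z, dtype=bool)
    keep[np.ix_(a, b)] = True
    keep[np.ix_(b, a)] = True
    np.fill_diagonal(keep, False)
    if not keep.any():
        raise ValueError(f"seed {seed.name!r}: empty connection set")
    mask = dysconnection_mask(mat, norm) & keep
    scope_regions = sorted(set(a) | set(b))
    dcc = mask[scope_regions].sum()
    return DCISummary(
        subject_id=mat.subject_id,
        session=mat.session,
        scope=seed.name,
        hemisphere=mat.hemisphere,
        dci=float(dcc) / len(scope_regions),
    )


def dcc_change_map(
    subject_id: str,
    cohort_dccs: pd.DataFrame,
    sd_floor: float = SD_FLOOR,
) -> ChangeMap:
    """Standardise DCC per region across the cohort, then baseline - follow-up.

    ``cohort_dccs`` is a tidy frame with columns ``subject, session`` plus one
    column per region, containing every participant at both sessions (the
    normalisation population). Standardisation pools both sessions. Positive
    output = reduced dysconnectivity at follow-up.
    """
    required = {"subject", "session"}
    if not required <= set(cohort_dccs.columns):
        raise ValueError("cohort_dccs needs 'subject' and 'session' columns")
    regions = [c for c in cohort_dccs.columns if c not in required]
    values = cohort_dccs[regions].to_numpy(dtype=float)
    z = (values - values.mean(axis=0)) / np.maximum(values.std(axis=0), sd_floor)
    zf = pd.DataFrame(z, columns=regions)
    zf["subject"] = cohort_dccs["subject"].values
    zf["session"] = cohort_dccs["session"].values
    rows = zf[zf["subject"] == subject_id]
    base = rows[rows["session"] == "baseline"]
    follow = rows[rows["session"] == "followup"]
    if len(base) != 1 or len(follow) != 1:
        raise ValueError(f"subject {subject_id!r} must appear exactly once per session")
    delta = pd.Series(
        base[regions].to_numpy()[0] - follow[regions].to_numpy()[0],
        index=regions, name="delta_dcc",
    )
    return ChangeMap(subject_id=subject_id, delta_dcc=delta)


# ---------------------------------------------------------------------------
# scope assembly and cohort-level pipeline helpers


def default_seed_definitions(region_meta: pd.DataFrame) -> list[SeedDefinition]:
    """The twelve specific scopes: eight networks and four anatomical seeds.

    Together with the whole-brain DCI these form the thirteen outcomes of the
    longitudinal model battery: each canonical network within itself, the
    hippocampal formation within itself, hippocampal-formation <-> prefrontal,
    thalamus <-> middle frontal, and thalamus <-> somatomotor.
    """
    def members(network: str) -> list[str]:
        out = list(region_meta.loc[region_meta["network"] == network, "region_id"])
        if not out:
            raise ValueError(f"no regions labelled {network!r}")
        return out

    networks = ["visual", "somatomotor", "limbic", "frontoparietal",
                "default-mode", "dorsal-attention", "salience", "subcortical"]
    seeds = [SeedDefinition(name=n, region_set_a=members(n)) for n in networks]
    seeds.append(SeedDefinition("hippocampal-formation", members("hippocampal-formation")))
    seeds.append(SeedDefinition("hippocampus-prefrontal",
                                members("hippocampal-formation"), members("prefrontal")))
    seeds.append(SeedDefinition("thalamus-middle-frontal",
                                members("thalamus"), members("middle-frontal")))
    seeds.append(SeedDefinition("thalamus-somatomotor",
                                members("thalamus"), members("somatomotor")))
    return seeds


def score_subject(
    mats: tuple[ConnectivityMatrix, ConnectivityMatrix],
    norms: dict[str, ReferenceNorm],
    seeds: list[SeedDefinition] | None = None,
) -> tuple[list[DCISummary], list[DCCMap]]:
    """Whole-brain and seed-specific DCIs plus DCC maps for one subject."""
    summaries: list[DCISummary] = []
    dccs: list[DCCMap] = []
    for mat in mats:
        norm = norms[mat.hemisphere]
        mask = dysconnection_mask(mat, norm)
        dm = dcc_map(mask, mat.region_ids, mat.subject_id, mat.session, mat.hemisphere)
        dccs.append(dm)
        summaries.append(whole_brain_dci(dm))
        for seed in seeds or []:
            summaries.append(specific_dci(mat, seed, norm))
    return summaries, dccs


def dci_table(summaries: list[DCISummary]) -> pd.DataFrame:
    """Tidy frame (subject, session, hemisphere, scope, dci)."""
    return pd.DataFrame(
        [
            {"subject": s.subject_id, "session": s.session,
             "hemisphere": s.hemisphere, "scope": s.scope, "dci": s.dci}
            for s in summaries
        ]
    )


def score_cohort(
    study,
    threshold_k: float = 2.0,
    calibration: str = "predictive",
) -> tuple[dict[str, ReferenceNorm], pd.DataFrame, pd.DataFrame]:
    """Full scoring pipeline for a synthetic study.

    Fits the reference norm on the study's healthy cohort, then scores every
    patient session: returns the per-hemisphere norms, the tidy DCI table
    (whole-brain plus all default seed scopes) and the wide per-region DCC
    table. Time series are used as generated (the generator's default output
    is stationary and trend-free, so connectivity is computed directly).
    """
    from .connectivity import connectivity_from_dataframe

    meta = study.spec.region_meta
    ref_mats = [
        connectivity_from_dataframe(ts, meta, f"ref-{i + 1:03d}", "baseline",
                                    tr_seconds=study.spec.tr_seconds)
        for i, ts in enumerate(study.reference_timeseries)
    ]
    norms = {
        hemi: fit_reference_norm(
            [pair[j] for pair in ref_mats], threshold_k=threshold_k,
            calibration=calibration,
        )
        for j, hemi in enumerate(("L", "R"))
    }
    seeds = default_seed_definitions(meta)
    summaries: list[DCISummary] = []
    dccs: list[DCCMap] = []
    for (sub, ses), ts in study.patient_timeseries.items():
        mats = connectivity_from_dataframe(ts, meta, sub, ses,
                                           tr_seconds=study.spec.tr_seconds)
        s, d = score_subject(mats, norms, seeds)
        summaries += s
        dccs += d
    return norms, dci_table(summaries), dcc_table(dccs)


def dcc_table(dccs: list[DCCMap]) -> pd.DataFrame:
    """Wide frame: one row per (subject, session), one column per region."""
    rows: dict[tuple[str, str], dict] = {}
    for dm in dccs:
        key = (dm.subject_id, dm.session)
        rows.setdefault(key, {"subject": dm.subject_id, "session": dm.session})
        rows[key].update(dm.dcc.to_dict())
    return pd.DataFrame(list(rows.values()))
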