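"""Plain-text readers/writers: TSV tables, matrices with JSON sidecars, GMT."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .simulate import SyntheticStudy


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    """Rows = timepoints, columns = regions, tab-delimited with header."""
    df.to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Materialise a synthetic study as delimited text plus a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.spec.region_meta.to_csv(out / "region_meta.tsv", sep="\t", index=False)
    study.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    for i, ts in enumerate(study.reference_timeseries):
        write_timeseries(ts, out / f"ref-{i + 1:03d}_timeseries.tsv")
    for (sub, ses), ts in study.patient_timeseries.items():
        write_timeseries(ts, out / f"{sub}_{ses}_timeseries.tsv")
    truth = {
        "effects": [
            {"target": e.target, "baseline_shift": e.baseline_shift,
             "attenuation": e.attenuation, "direction": e.direction}
            for e in study.effects
        ],
        "subject_scale": study.subject_scale.to_dict(),
        "true_network_change": {
            s: study.true_network_change.loc[s].to_dict() for s in study.subjects
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    """Delimited matrix plus a JSON sidecar with hemisphere and region order."""
    path = Path(path)
    np.savetxt(path, mat.z, delimiter="\t")
    sidecar = {
        "subject_id": mat.subject_id,
        "session": mat.session,
        "hemisphere": mat.hemisphere,
        "region_ids": mat.region_ids,
        "scale": "fisher-z",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    z = np.loadtxt(path, delimiter="\t")
    return ConnectivityMatrix(
        subject_id=meta["subject_id"], session=meta["session"],
        hemisphere=meta["hemisphere"], z=z, region_ids=meta["region_ids"],
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              description: str = "synthetic cell-type set") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
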