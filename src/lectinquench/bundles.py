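"""On-disk dataset bundles: directories of CSV spectra plus one manifest.

Layout written by :func:`write_bundle` and consumed by the CLI:

    bundle/
      manifest.csv        one row per file: file, kind, label, temperature_K,
                          quencher_M, urea_M, replicate, protein_conc_M,
                          path_cm, n_residues
      truth.json          generating parameters (present for synthetic data)
      titration/*.csv     wavelength_nm,intensity  (kind emission_f0/emission)
      denat/*.csv         wavelength_nm,intensity  (kind emission_denat)
      cd/*.csv            wavelength_nm,ellipticity_mdeg
      ha/*.csv            dilution_factor,positive (0/1)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .denaturation import DenaturationRecord, HAPlate
from .spectra import CDSpectrum, EmissionSpectrum, TitrationSeries, read_spectrum, write_spectrum

__all__ = ["Bundle", "write_bundle", "load_bundle"]

_MANIFEST_COLS = [
    "file", "kind", "label", "temperature_K", "quencher_M", "urea_M",
    "replicate", "protein_conc_M", "path_cm", "n_residues",
]


@dataclass
class Bundle:
    titrations: dict = field(default_factory=dict)   # label -> [TitrationSeries]
    denaturation: list = field(default_factory=list)  # [DenaturationRecord]
    truth: dict = field(default_factory=dict)


def _row(file, kind, label=None, **kw):
    row = {c: None for c in _MANIFEST_COLS}
    row.update(file=file, kind=kind, label=label, **kw)
    return row


def write_bundle(path, titrations: dict | None = None,
                 denaturation: list | None = None,
                 truth: dict | None = None) -> Path:
    """Write titration series and/or denaturation records plus manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, series_list in (titrations or {}).items():
        sub = root / "titration"
        sub.mkdir(exist_ok=True)
        for series in series_list:
            t = series.temperature_K
            f0name = f"titration/{label}_T{t:.0f}_f0.csv"
            write_spectrum(series.f0, root / f0name)
            rows.append(_row(f0name, "emission_f0", label, temperature_K=t, quencher_M=0.0))
            for i, (q, spec) in enumerate(series.points):
                name = f"titration/{label}_T{t:.0f}_q{i:02d}.csv"
                write_spectrum(spec, root / name)
                rows.append(_row(name, "emission", label, temperature_K=t, quencher_M=q))
    for rec in denaturation or []:
        (root / "denat").mkdir(exist_ok=True)
        for r, spec in enumerate(rec.spectra, start=1):
            name = f"denat/u{rec.urea_M:g}_r{r}.csv"
            write_spectrum(spec, root / name)
            rows.append(_row(name, "emission_denat", urea_M=rec.urea_M, replicate=r))
        if rec.cd is not None:
            (root / "cd").mkdir(exist_ok=True)
            name = f"cd/u{rec.urea_M:g}.csv"
            with open(root / name, "w") as fh:
                fh.write("wavelength_nm,ellipticity_mdeg\n")
                for x, y in zip(rec.cd.wavelengths, rec.cd.signal):
                    fh.write(f"{float(x)!r},{float(y)!r}\n")
            rows.append(_row(name, "cd", urea_M=rec.urea_M,
                             protein_conc_M=rec.cd.protein_conc_M,
                             path_cm=rec.cd.path_cm, n_residues=rec.cd.n_residues))
        if rec.ha is not None:
            (root / "ha").mkdir(exist_ok=True)
            name = f"ha/u{rec.urea_M:g}.csv"
            with open(root / name, "w") as fh:
                fh.write("dilution_factor,positive\n")
                for d, w in zip(rec.ha.dilutions, rec.ha.wells):
                    fh.write(f"{d},{int(w)}\n")
            rows.append(_row(name, "ha", urea_M=rec.urea_M))
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(root / "manifest.csv", index=False)
    if truth is not None:
        (root / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=2))
    return root


def _notnull(v):
    return v is not None and not (isinstance(v, float) and math.isnan(v))


def load_bundle(path) -> Bundle:
    root = Path(path)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    df = pd.read_csv(manifest)
    bundle = Bundle()
    truth_file = root / "truth.json"
    if truth_file.exists():
        bundle.truth = json.loads(truth_file.read_text())

    tit = df[df.kind.isin(["emission_f0", "emission"])]
    for label, g in tit.groupby("label"):
        series_list = []
        for t, gt in g.groupby("temperature_K"):
            f0_rows = gt[gt.kind == "emission_f0"]
            if len(f0_rows) != 1:
                raise ValueError(f"label {label} T={t}: need exactly one F0 spectrum")
            f0 = read_spectrum(root / f0_rows.iloc[0].file,
                               meta={"temperature_K": t, "quencher_M": 0.0})
            pts = []
            for _, row in gt[gt.kind == "emission"].sort_values("quencher_M").iterrows():
                spec = read_spectrum(root / row.file,
                                     meta={"temperature_K": t, "quencher_M": row.quencher_M})
                pts.append((float(row.quencher_M), spec))
            series_list.append(TitrationSeries(f0, tuple(pts), float(t)))
        bundle.titrations[label] = sorted(series_list, key=lambda s: s.temperature_K)

    den = df[df.kind == "emission_denat"]
    if len(den):
        for u, gu in den.groupby("urea_M"):
            specs = tuple(
                read_spectrum(root / row.file,
                              meta={"urea_M": u, "replicate": row.replicate})
                for _, row in gu.sort_values("replicate").iterrows()
            )
            cd = ha = None
            cd_rows = df[(df.kind == "cd") & (df.urea_M == u)]
            if len(cd_rows):
                r = cd_rows.iloc[0]
                tbl = pd.read_csv(root / r.file)
                cd = CDSpectrum(
                    tbl.iloc[:, 0].to_numpy(), tbl.iloc[:, 1].to_numpy(),
                    protein_conc_M=r.protein_conc_M if _notnull(r.protein_conc_M) else None,
                    path_cm=r.path_cm if _notnull(r.path_cm) else None,
                    n_residues=int(r.n_residues) if _notnull(r.n_residues) else None,
                    meta={"urea_M": u},
                )
            ha_rows = df[(df.kind == "ha") & (df.urea_M == u)]
            if len(ha_rows):
                tbl = pd.read_csv(root / ha_rows.iloc[0].file)
                ha = HAPlate(tuple(bool(v) for v in tbl.iloc[:, 1]),
                             start_dilution=int(tbl.iloc[0, 0]))
            bundle.denaturation.append(DenaturationRecord(float(u), specs, cd=cd, ha=ha))
        bundle.denaturation.sort(key=lambda r: r.urea_M)
    return bundle
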