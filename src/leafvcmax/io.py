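"""Plain-text readers and writers for spectra, SAC tables and datasets.

Spectra are two-column delimited text (wavelength_nm, value) with a
one-line header.  A SAC set is a wide table keyed by constituent name.
A dataset directory holds a YAML manifest naming each step's spectrum
files together with the forcing values, a forcing table, a PAM table,
optional reference spectra and an optional truth file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biochem import Forcing
from .errors import DataError
from .leaf_rt import SACSet
from .retrieval import PAMRecord, ResponseCurveDataset, StepSpectra
from .spectra import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_sacs",
    "write_sacs",
    "write_dataset",
    "read_dataset",
]

_SAC_COLUMNS = [
    "wavelength_nm", "cab", "ccar", "cant", "cw", "cdm", "cs",
    "cx_band", "refractive", "phi",
]


def write_spectrum(path, spectrum: Spectrum, value_name: str = "value") -> None:
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, value_name: spectrum.values}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_spectrum(path) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two columns (wavelength, value)")
    return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def write_sacs(path, sacs: SACSet) -> None:
    df = pd.DataFrame(
        {
            "wavelength_nm": sacs.wavelengths,
            "cab": sacs.cab, "ccar": sacs.ccar, "cant": sacs.cant,
            "cw": sacs.cw, "cdm": sacs.cdm, "cs": sacs.cs,
            "cx_band": sacs.cx_band, "refractive": sacs.refractive,
            "phi": sacs.phi,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_sacs(path) -> SACSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SAC_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing SAC columns {missing}")
    return SACSet(
        df["wavelength_nm"].to_numpy(),
        df["cab"].to_numpy(), df["ccar"].to_numpy(), df["cant"].to_numpy(),
        df["cw"].to_numpy(), df["cdm"].to_numpy(), df["cs"].to_numpy(),
        df["cx_band"].to_numpy(), df["refractive"].to_numpy(),
        df["phi"].to_numpy(),
    )


def _forcing_frame(steps) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ipar": [s.ipar for s in steps],
            "t_leaf": [s.t_leaf for s in steps],
            "cs_air": [s.cs_air for s in steps],
            "rh": [s.rh for s in steps],
        }
    )


def write_dataset(directory, ds: ResponseCurveDataset) -> None:
    """Write a dataset directory: manifest + forcing + spectra + PAM."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {"kind": ds.kind, "steps": []}

    _forcing_frame(ds.steps).to_csv(d / "forcing.tsv", sep="\t", index=False)

    if ds.a_meas is not None:
        pd.DataFrame({"a": np.asarray(ds.a_meas)}).to_csv(
            d / "assimilation.tsv", sep="\t", index=False
        )
        manifest["assimilation"] = "assimilation.tsv"
    if ds.pam is not None:
        pd.DataFrame(
            {"fs": ds.pam.fs, "fm_prime": ds.pam.fm_prime}
        ).to_csv(d / "pam.tsv", sep="\t", index=False)
        manifest["pam"] = {
            "table": "pam.tsv",
            "fo_dark": float(ds.pam.fo_dark),
            "fm_dark": float(ds.pam.fm_dark),
        }
    for i, step in enumerate(ds.steps):
        entry = {
            "ipar": step.ipar, "t_leaf": step.t_leaf,
            "cs_air": step.cs_air, "rh": step.rh,
        }
        if ds.spectra is not None:
            sp = ds.spectra[i]
            for name in ("rho", "tau", "chlf_forward", "chlf_backward"):
                s = getattr(sp, name)
                if s is not None:
                    fname = f"step{i:02d}_{name}.tsv"
                    write_spectrum(d / fname, s, value_name=name)
                    entry[name] = fname
        manifest["steps"].append(entry)
    for name in ("reference_rho", "reference_tau"):
        s = getattr(ds, name)
        if s is not None:
            fname = f"{name}.tsv"
            write_spectrum(d / fname, s, value_name=name)
            manifest[name] = fname
    if ds.truth is not None:
        truth = ds.truth
        truth_doc = {
            "seed": truth.seed,
            "noise": dict(truth.noise),
            "optical": {
                k: float(getattr(truth.optical, k))
                for k in ("cab", "ccar", "cant", "cw", "cdm", "n_layers",
                          "cs", "eta", "cx")
            },
            "biochem": {
                k: float(getattr(truth.biochem, k))
                for k in ("vcmax", "m", "rd_param", "kn0", "beta", "gamma")
            },
            "coupling": {
                "slope_cx": float(truth.coupling.slope_cx),
                "sigma_scale": float(truth.coupling.sigma_scale),
            },
        }
        (d / "truth.yaml").write_text(yaml.safe_dump(truth_doc))
        manifest["truth"] = "truth.yaml"
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_dataset(directory) -> ResponseCurveDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    d = Path(directory)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    steps, spectra = [], []
    any_spectra = False
    for entry in manifest["steps"]:
        steps.append(
            Forcing(
                ipar=float(entry["ipar"]), t_leaf=float(entry["t_leaf"]),
                cs_air=float(entry["cs_air"]), rh=float(entry["rh"]),
            )
        )
        sp = StepSpectra()
        for name in ("rho", "tau", "chlf_forward", "chlf_backward"):
            if name in entry:
                setattr(sp, name, read_spectrum(d / entry[name]))
                any_spectra = True
        spectra.append(sp)
    a_meas = None
    if "assimilation" in manifest:
        a_meas = pd.read_csv(d / manifest["assimilation"], sep="\t")["a"].to_numpy()
    pam = None
    if "pam" in manifest:
        tbl = pd.read_csv(d / manifest["pam"]["table"], sep="\t")
        pam = PAMRecord(
            fs=tbl["fs"].to_numpy(),
            fm_prime=tbl["fm_prime"].to_numpy(),
            fo_dark=float(manifest["pam"]["fo_dark"]),
            fm_dark=float(manifest["pam"]["fm_dark"]),
        )
    ref_rho = ref_tau = None
    if "reference_rho" in manifest:
        ref_rho = read_spectrum(d / manifest["reference_rho"])
    if "reference_tau" in manifest:
        ref_tau = read_spectrum(d / manifest["reference_tau"])
    return ResponseCurveDataset(
        kind=manifest["kind"],
        steps=steps,
        a_meas=a_meas,
        pam=pam,
        spectra=spectra if any_spectra else None,
        reference_rho=ref_rho,
        reference_tau=ref_tau,
    )
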