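"""Input parsing: PSM tables (TSV), spectra (MGF / mzML), experiment assembly.

The PSM-table reader accepts the MSFragger/Philosopher ``PSM.tsv`` column
names by default and takes a user-overridable column map.  Spectrum keys use
a run-name + scan-number composite so MGF TITLE lines and mzML scan ids
resolve to the same convention.

MGF and mzML support is implemented here with the standard library (no
dedicated mass-spectrometry parser is available in the deployment
environment).  The mzML support is deliberately minimal: uncompressed or
zlib-compressed 32/64-bit little-endian m/z and intensity arrays, which is
what this package's own writer emits and what MSConvert produces for
centroided data.
"""

from __future__ import annotations

import base64
import os
import struct
import warnings
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RowParseError
from .model import ExperimentSet, PSMRecord, Spectrum

# Philosopher PSM.tsv naming.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "spectrum_id": "Spectrum",
    "peptide": "Peptide",
    "delta_mass": "Delta Mass",
    "retention_time": "Retention",
    "charge": "Charge",
    "proteins": "Protein",
}

MANDATORY_FIELDS = ("spectrum_id", "peptide", "delta_mass", "retention_time", "charge")


def read_psm_table(
    path: str | os.PathLike,
    experiment: str,
    column_map: dict[str, str] | None = None,
    rt_unit: str = "seconds",
) -> list[PSMRecord]:
    """Parse one PSM table into records, preserving file order.

    ``rt_unit`` may be ``"seconds"`` (default) or ``"minutes"``; retention
    times are normalized to seconds on load.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if rt_unit not in ("seconds", "minutes"):
        raise ConfigurationError("rt_unit must be 'seconds' or 'minutes'")
    rt_scale = 60.0 if rt_unit == "minutes" else 1.0

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field in MANDATORY_FIELDS:
        if cmap[field] not in df.columns:
            raise ConfigurationError(
                f"PSM table {path} lacks mandatory column '{cmap[field]}' "
                f"(field '{field}')"
            )
    have_proteins = cmap["proteins"] in df.columns

    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            delta = float(row_d[cmap["delta_mass"]])
            rt = float(row_d[cmap["retention_time"]]) * rt_scale
            charge = int(float(row_d[cmap["charge"]]))
        except ValueError as exc:
            raise RowParseError(i, str(exc)) from exc
        proteins = []
        if have_proteins and row_d[cmap["proteins"]]:
            proteins = [p.strip() for p in row_d[cmap["proteins"]].split(",")]
        records.append(
            PSMRecord(
                spectrum_id=row_d[cmap["spectrum_id"]],
                experiment=experiment,
                peptide=row_d[cmap["peptide"]].upper(),
                delta_mass=delta,
                retention_time=rt,
                charge=charge,
                proteins=proteins,
            )
        )
    return records


def write_psm_table(path: str | os.PathLike, records: list[PSMRecord]) -> None:
    """Serialize records with the default column names (fixed precision)."""
    with open(path, "w") as fh:
        fh.write("Spectrum\tPeptide\tDelta Mass\tRetention\tCharge\tProtein\n")
        for r in records:
            fh.write(
                f"{r.spectrum_id}\t{r.peptide}\t{r.delta_mass:.6f}\t"
                f"{r.retention_time:.4f}\t{r.charge}\t{','.join(r.proteins)}\n"
            )


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | os.PathLike) -> dict[str, Spectrum]:
    """Read an MGF file; spectrum keys come from TITLE lines."""
    spectra: dict[str, Spectrum] = {}
    title: str | None = None
    mzs: list[float] = []
    ints: list[float] = []
    in_block = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                title = None
                mzs, ints = [], []
            elif line == "END IONS":
                if title is None:
                    title = f"scan={len(spectra) + 1}"
                spectra[title] = Spectrum(title, np.array(mzs), np.array(ints))
                in_block = False
            elif in_block:
                if "=" in line and not line[0].isdigit():
                    key, _, value = line.partition("=")
                    if key == "TITLE":
                        title = value.strip()
                else:
                    parts = line.split()
                    mzs.append(float(parts[0]))
                    ints.append(float(parts[1]))
    return spectra


def write_mgf(path: str | os.PathLike, spectra: list[Spectrum]) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            for mz, inten in zip(sp.mz, sp.intensity):
                fh.write(f"{mz:.5f} {inten:.4f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# mzML (minimal)
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MZ = "MS:1000514"
_ACC_INT = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    kind = None
    dtype = "<f8"
    compressed = False
    for cv in bda.iter():
        if not cv.tag.endswith("cvParam"):
            continue
        acc = cv.get("accession", "")
        if acc == _ACC_MZ:
            kind = "mz"
        elif acc == _ACC_INT:
            kind = "intensity"
        elif acc == _ACC_F32:
            dtype = "<f4"
        elif acc == _ACC_F64:
            dtype = "<f8"
        elif acc == _ACC_ZLIB:
            compressed = True
    node = bda.find(f"{_NS}binary")
    if node is None:
        node = bda.find("binary")
    text = (node.text or "") if node is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | os.PathLike) -> dict[str, Spectrum]:
    """Read a minimal mzML file; keys are ``<run>.<scan>`` composites."""
    run_name = Path(path).stem
    spectra: dict[str, Spectrum] = {}
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if not elem.tag.endswith("spectrum"):
            continue
        sid = elem.get("id", "")
        scan = None
        for token in sid.split():
            if token.startswith("scan="):
                scan = token[5:]
        key = f"{run_name}.{scan}" if scan is not None else f"{run_name}.{sid}"
        mz = np.empty(0)
        inten = np.empty(0)
        for bda in elem.iter():
            if bda.tag.endswith("binaryDataArray"):
                kind, arr = _decode_binary(bda)
                if kind == "mz":
                    mz = arr
                elif kind == "intensity":
                    inten = arr
        spectra[key] = Spectrum(key, mz, inten)
        elem.clear()
    return spectra


def write_mzml(path: str | os.PathLike, spectra: list[Spectrum], run_id: str | None = None) -> None:
    """Write a minimal mzML file (64-bit little-endian, uncompressed).

    Spectrum ids are emitted as ``scan=N`` in input order so that
    :func:`read_mzml` reconstructs ``<file stem>.<N>`` keys.  For round-trip
    fidelity, name the file after the run and key spectra ``<run>.<N>``.
    """
    run_id = run_id or Path(path).stem

    def b64(arr: np.ndarray) -> str:
        return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="utf-8"?>\n')
        fh.write('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n')
        fh.write(f'  <run id="{run_id}">\n')
        fh.write(f'    <spectrumList count="{len(spectra)}">\n')
        for i, sp in enumerate(spectra):
            n = len(sp)
            scan = sp.spectrum_id.rsplit(".", 1)[-1] if "." in sp.spectrum_id else str(i + 1)
            fh.write(
                f'      <spectrum index="{i}" id="scan={scan}" defaultArrayLength="{n}">\n'
            )
            fh.write('        <cvParam accession="MS:1000511" name="ms level" value="2"/>\n')
            fh.write('        <binaryDataArrayList count="2">\n')
            for acc, name, arr in (
                (_ACC_MZ, "m/z array", sp.mz),
                (_ACC_INT, "intensity array", sp.intensity),
            ):
                fh.write("          <binaryDataArray>\n")
                fh.write(f'            <cvParam accession="{_ACC_F64}" name="64-bit float"/>\n')
                fh.write('            <cvParam accession="MS:1000576" name="no compression"/>\n')
                fh.write(f'            <cvParam accession="{acc}" name="{name}"/>\n')
                fh.write(f"            <binary>{b64(arr)}</binary>\n")
                fh.write("          </binaryDataArray>\n")
            fh.write("        </binaryDataArrayList>\n")
            fh.write("      </spectrum>\n")
        fh.write("    </spectrumList>\n")
        fh.write("  </run>\n")
        fh.write("</mzML>\n")


def read_spectra(path: str | os.PathLike) -> dict[str, Spectrum]:
    """Dispatch on extension: ``.mgf`` or ``.mzml``."""
    ext = Path(path).suffix.lower()
    if ext == ".mgf":
        return read_mgf(path)
    if ext == ".mzml":
        return read_mzml(path)
    raise ConfigurationError(f"unknown spectrum file extension '{ext}' for {path}")


# ---------------------------------------------------------------------------
# Experiment assembly
# ---------------------------------------------------------------------------

def assemble_experiment_set(
    psm_tables: list[tuple[str | os.PathLike, str]],
    spectra_paths: list[str | os.PathLike] = (),
    column_map: dict[str, str] | None = None,
    rt_unit: str = "seconds",
) -> ExperimentSet:
    """Read all tables and spectra into one :class:`ExperimentSet`.

    PSMs whose spectrum key does not resolve are retained (they still count
    for the histogram and quantification) but flagged in
    ``missing_spectra`` and excluded from localization/similarity; a warning
    is emitted.
    """
    if not psm_tables:
        raise ConfigurationError("at least one PSM table is required")
    labels = [label for _, label in psm_tables]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate experiment labels: {labels}")

    es = ExperimentSet()
    for path, label in psm_tables:
        es.experiments[label] = read_psm_table(path, label, column_map, rt_unit)
    for spath in spectra_paths:
        es.spectra.update(read_spectra(spath))

    if es.spectra or spectra_paths:
        for psm in es.all_psms():
            if psm.spectrum_id not in es.spectra:
                es.missing_spectra.add(psm.spectrum_id)
        if es.missing_spectra:
            warnings.warn(
                f"{len(es.missing_spectra)} PSM spectrum id(s) did not resolve; "
                "those PSMs are excluded from localization and similarity",
                stacklevel=2,
            )
    return es
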