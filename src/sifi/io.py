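"""Delimited-text I/O, spectroscopy constants and run configuration.

All tabular artefacts (decays, IRFs, traces, dwell tables, fit reports,
profile tables) are plain delimited text with a ``# key: value`` metadata
header, so every intermediate is inspectable and diffable. Readers preserve
unknown header keys; writers always record the package version and, where
applicable, the simulation seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .histogram import DecayHistogram
from .smkinetics import IntensityTrace

__all__ = [
    "read_decay",
    "write_decay",
    "read_trace",
    "write_trace",
    "write_profile_dataset",
    "read_profile_dataset",
    "write_fit_report",
    "write_table",
    "beer_lambert_concentration",
    "EPSILON_CY3",
    "InnerFilterWarning",
    "FormatError",
    "read_duplex_spec",
    "RunConfig",
    "load_run_config",
]

#: Molar absorption coefficient of Cy3 at 550 nm, M^-1 cm^-1.
EPSILON_CY3 = 150_000.0

#: Absorbance above which inner-filter effects distort intensity readings.
INNER_FILTER_LIMIT = 0.1


class FormatError(ValueError):
    """A malformed text file; the message carries the offending line number."""


class InnerFilterWarning(UserWarning):
    """Absorbance too high for inner-filter-free fluorescence measurements."""


def _format_value(v):
    if isinstance(v, (list, tuple, np.ndarray)):
        return json.dumps([float(x) for x in v])
    if isinstance(v, (np.floating, np.integer)):
        return repr(v.item())
    return str(v)


def _parse_value(s: str):
    s = s.strip()
    for caster in (int, float):
        try:
            return caster(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    if s == "None":
        return None
    if s.startswith("[") or s.startswith("{"):
        try:
            return json.loads(s)
        except json.JSONDecodeError:
            pass
    return s


def _write_header(fh, meta: dict, kind: str) -> None:
    from . import __version__

    fh.write(f"# sifi {kind} v{__version__}\n")
    for k, v in meta.items():
        fh.write(f"# {k}: {_format_value(v)}\n")


def _read_header(lines):
    """Parse leading '# key: value' lines; returns (metadata, first data line index)."""
    meta = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if ":" in body:
            k, _, v = body.partition(":")
            meta[k.strip()] = _parse_value(v)
    else:
        i = len(lines)
    return meta, i


# ---------------------------------------------------------------------------
# decays


def write_decay(hist: DecayHistogram, path) -> None:
    """Write a decay/IRF as two-column text (channel index, counts)."""
    meta = dict(hist.metadata)
    meta.setdefault("channel_width_ps", hist.channel_width * 1e3)
    meta["kind"] = hist.kind
    with open(path, "w") as fh:
        _write_header(fh, meta, "decay")
        for i, c in enumerate(hist.counts):
            if c == int(c):
                fh.write(f"{i}\t{int(c)}\n")
            else:
                fh.write(f"{i}\t{float(c)!r}\n")


def read_decay(path) -> DecayHistogram:
    """Read a decay/IRF text file; lossless metadata round-trip.

    ``channel_width_ps`` is required in the header; unknown keys are kept in
    the metadata map. Format violations raise :class:`FormatError` with the
    line number.
    """
    lines = Path(path).read_text().splitlines()
    meta, start = _read_header(lines)
    if "channel_width_ps" not in meta:
        raise FormatError(f"{path}: missing required header key channel_width_ps")
    counts = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected 'channel counts', got {line!r}")
        try:
            value = float(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{ln}: non-numeric counts {parts[1]!r}") from None
        if value < 0:
            raise FormatError(f"{path}:{ln}: negative counts")
        counts.append(value)
    kind = meta.pop("kind", "decay")
    width_ps = meta.pop("channel_width_ps")
    return DecayHistogram(
        channel_width=float(width_ps) / 1e3,
        counts=np.asarray(counts),
        kind=kind,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# traces


def write_trace(trace: IntensityTrace, path) -> None:
    meta = {
        k: v
        for k, v in trace.metadata.items()
        if isinstance(v, (int, float, str, bool, type(None)))
    }
    meta["frame_time_s"] = trace.frame_time
    with open(path, "w") as fh:
        _write_header(fh, meta, "trace")
        has_truth = trace.truth_state is not None
        fh.write("# columns: frame\tintensity" + ("\ttruth_state\n" if has_truth else "\n"))
        for i, x in enumerate(trace.intensities):
            row = f"{i}\t{float(x)!r}"
            if has_truth:
                row += f"\t{int(trace.truth_state[i])}"
            fh.write(row + "\n")


def read_trace(path) -> IntensityTrace:
    lines = Path(path).read_text().splitlines()
    meta, start = _read_header(lines)
    if "frame_time_s" not in meta:
        raise FormatError(f"{path}: missing required header key frame_time_s")
    intensities, truth = [], []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}:{ln}: expected 2 or 3 columns")
        intensities.append(float(parts[1]))
        if len(parts) == 3:
            truth.append(int(parts[2]))
    frame_time = float(meta.pop("frame_time_s"))
    return IntensityTrace(
        frame_time=frame_time,
        intensities=np.asarray(intensities),
        truth_state=np.asarray(truth) if truth else None,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# profile datasets


def write_profile_dataset(dataset, directory) -> None:
    """Write a decays-mode profile dataset: decay files plus a manifest.

    Layout: ``irf.txt``, one decay file per (position, experiment,
    replicate) and ``manifest.tsv`` mapping file -> measurement; the
    generator configuration is stored in the manifest header.
    """
    if dataset.mode != "decays":
        raise ValueError("only decays-mode datasets have a file representation")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_decay(dataset.irf, directory / "irf.txt")
    rows = []
    for (pos, exp, rep), decay in dataset.decays.items():
        name = f"pos{pos:02d}_exp{exp}_rep{rep:02d}.txt"
        write_decay(decay, directory / name)
        rows.append((name, pos, exp, rep))
    with open(directory / "manifest.tsv", "w") as fh:
        meta = {"config": json.dumps(asdict(dataset.config))}
        _write_header(fh, meta, "profile-manifest")
        fh.write("filename\tposition\texperiment\treplicate\n")
        for row in sorted(rows):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_profile_dataset(directory):
    """Read a profile dataset directory written by :func:`write_profile_dataset`."""
    from .simulate import NearFieldDip, PositionProfileDataset, ProfileSimConfig

    directory = Path(directory)
    lines = (directory / "manifest.tsv").read_text().splitlines()
    meta, start = _read_header(lines)
    config = None
    if "config" in meta:
        raw = meta["config"] if isinstance(meta["config"], dict) else json.loads(meta["config"])
        raw["positions"] = tuple(raw.get("positions", ()))
        raw["nearfield_dip"] = NearFieldDip(**raw["nearfield_dip"])
        config = ProfileSimConfig(**raw)
    irf = read_decay(directory / "irf.txt")
    decays = {}
    header_seen = False
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        name, pos, exp, rep = line.split("\t")
        decays[(int(pos), int(exp), int(rep))] = read_decay(directory / name)
    return PositionProfileDataset(
        config=config,
        table=pd.DataFrame(),
        mode="decays",
        irf=irf,
        decays=decays,
    )


# ---------------------------------------------------------------------------
# reports


def write_fit_report(fit, path, extra_meta: Optional[dict] = None) -> None:
    """Serialise a decay fit as a flat key:value table plus component rows."""
    from .tcspc import fractional_intensities

    meta = {
        "n_components": fit.n_components,
        "chi2_reduced": fit.chi2_reduced,
        "background": fit.background,
        "irf_shift_channels": fit.irf_shift,
        "tau_amp_ns": fit.amp_weighted,
        "tau_int_ns": fit.intensity_weighted,
    }
    if getattr(fit, "flags", None):
        meta["flags"] = ",".join(fit.flags)
    if extra_meta:
        meta.update(extra_meta)
    amp_frac = fit.amplitudes / fit.amplitudes.sum()
    f = fractional_intensities(fit)
    with open(path, "w") as fh:
        _write_header(fh, meta, "fit-report")
        fh.write("component\ttau_ns\talpha\tf_intensity\n")
        for i, (t, a, fi) in enumerate(zip(fit.lifetimes, amp_frac, f), 1):
            fh.write(f"{i}\t{t:.6f}\t{a:.6f}\t{fi:.6f}\n")


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None, kind: str = "table") -> None:
    """Write a DataFrame as TSV with a key:value header."""
    with open(path, "w") as fh:
        _write_header(fh, meta or {}, kind)
        df.to_csv(fh, sep="\t", index=True, float_format="%.6g")


# ---------------------------------------------------------------------------
# spectroscopy


def beer_lambert_concentration(
    absorbance: float, epsilon: float = EPSILON_CY3, path_length: float = 1.0
) -> float:
    """Molar concentration from the Beer-Lambert law, c = A / (epsilon l).

    Warns if the absorbance exceeds 0.1, the working limit above which
    inner-filter effects bias fluorescence intensity measurements.
    """
    if epsilon <= 0 or path_length <= 0:
        raise ValueError("epsilon and path_length must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if absorbance > INNER_FILTER_LIMIT:
        warnings.warn(
            f"absorbance {absorbance:.3f} exceeds {INNER_FILTER_LIMIT}: "
            "inner-filter effects likely",
            InnerFilterWarning,
            stacklevel=2,
        )
    return absorbance / (epsilon * path_length)


# ---------------------------------------------------------------------------
# structured configuration


def read_duplex_spec(path):
    """Read a duplex/linker spec from YAML; returns (DuplexSpec, LinkerDyeParams)."""
    from .av import Attachment, DuplexSpec, Gap, LinkerDyeParams, Nick, Overhang

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "sequence" not in doc:
        raise FormatError(f"{path}: spec must be a mapping with a 'sequence' key")
    features = []
    for i, f in enumerate(doc.get("features", []) or []):
        ftype = f.get("type")
        try:
            if ftype == "nick":
                features.append(Nick(after=int(f["after"]), strand=f.get("strand", "B")))
            elif ftype == "gap":
                features.append(Gap(positions=tuple(f["positions"]), strand=f.get("strand", "B")))
            elif ftype == "overhang":
                features.append(
                    Overhang(
                        length=int(f["length"]),
                        polarity=f.get("polarity", "5p"),
                        strand=f.get("strand", "B"),
                    )
                )
            else:
                raise KeyError(f"unknown feature type {ftype!r}")
        except KeyError as exc:
            raise FormatError(f"{path}: features[{i}]: {exc}") from None
    attachment = None
    if "attachment" in doc:
        attachment = Attachment(
            strand=doc["attachment"].get("strand", "A"),
            position=int(doc["attachment"]["position"]),
            atom=doc["attachment"].get("atom", "C5"),
        )
    spec = DuplexSpec(
        sequence=doc["sequence"],
        sequence_b=doc.get("sequence_b"),
        rise=float(doc.get("rise", 3.4)),
        twist=float(doc.get("twist", 36.0)),
        features=tuple(features),
        attachment=attachment,
    )
    linker = LinkerDyeParams(**doc.get("linker", {}))
    return spec, linker


@dataclass
class RunConfig:
    """Top-level pipeline configuration for the ``run-all`` command."""

    seed: int = 0
    output_dir: str = "sifi-output"
    log_level: str = "INFO"
    instrument: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    trace: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    av_spec: Optional[str] = None


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration with precise error paths."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    for key in doc:
        if key not in known:
            raise FormatError(f"{path}: unknown configuration key '{key}'")
    for section in ("instrument", "fit", "trace", "profile"):
        if section in doc and not isinstance(doc[section], dict):
            raise FormatError(f"{path}: '{section}' must be a mapping")
    return RunConfig(**doc)
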