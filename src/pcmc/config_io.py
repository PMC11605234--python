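"""Config-file, profile, sample-set and trajectory I/O.

Systems are described by a versioned TOML schema (written by the fixture
generator, hand-editable); unknown keys are a hard error, never silently
ignored.  Profiles and sample sets are TSV files with JSON sidecars so that
every artifact carries its seed and system digest; configurations travel as
extended XYZ.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decomposition import Protocol
from .free_energy import PMFProfile
from .model import (
    Bond,
    CouplingMatrix,
    Configuration,
    CVSpec,
    MoleculeTemplate,
    SiteType,
    Species,
    SystemSpec,
)
from .oracle import TinySystem
from .sampler import BiasSpec, SampleSet

__all__ = [
    "ConfigBundle",
    "SchemaError",
    "read_config",
    "write_config",
    "generate_fixture",
    "write_profile",
    "read_profile",
    "write_samples",
    "read_samples",
    "write_xyz",
    "read_xyz",
    "write_manifest",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Config file violates the schema (with a path to the offending key)."""


@dataclass
class ConfigBundle:
    """Everything a config file describes."""

    system: SystemSpec
    protocol: Protocol | None
    roles: dict[str, str]  # solute_a / solute_b / solvent labels
    tiny: TinySystem | None


# ---------------------------------------------------------------------------
# TOML writing (minimal, deterministic emitter)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _emit_table(lines: list[str], name: str, table: dict) -> None:
    lines.append(f"[{name}]")
    for k, v in table.items():
        lines.append(f"{k} = {_toml_value(v)}")
    lines.append("")


def write_config(
    path: str | Path,
    system: SystemSpec,
    protocol: Protocol | None = None,
    roles: dict[str, str] | None = None,
    tiny: TinySystem | None = None,
) -> Path:
    """Write a system (plus optional protocol/roles/oracle grid) as TOML."""
    path = Path(path)
    lines: list[str] = [f"schema_version = {SCHEMA_VERSION}", ""]
    _emit_table(
        lines,
        "box",
        {
            "dimension": system.dimension,
            "length": system.box_length,
            "periodic": system.periodic,
        },
    )
    _emit_table(
        lines, "potential", {"cutoff": system.cutoff, "temperature": system.temperature}
    )
    if system.cv is not None:
        _emit_table(
            lines,
            "cv",
            {
                "kind": system.cv.kind,
                "species_a": system.cv.species_a,
                "species_b": system.cv.species_b,
                "site_a": system.cv.site_a,
                "site_b": system.cv.site_b,
            },
        )
    site_types: dict[str, SiteType] = {}
    for sp in system.species:
        for st in sp.template.sites:
            site_types[st.name] = st
    for name in sorted(site_types):
        st = site_types[name]
        _emit_table(
            lines,
            f"sites.{name}",
            {"epsilon": st.lj_epsilon, "sigma": st.lj_sigma, "charge": st.charge},
        )
    for sp in system.species:
        tpl = sp.template
        _emit_table(
            lines,
            f"species.{sp.label}",
            {
                "sites": [st.name for st in tpl.sites],
                "count": sp.n_molecules,
                "rigid": tpl.rigid,
                "geometry": [list(g) for g in tpl.geometry],
                "bonds": [[b.i, b.j, b.k, b.r0] for b in tpl.bonds],
            },
        )
    _emit_table(
        lines,
        "coupling",
        {"pairs": [[a, b, lam] for (a, b), lam in system.coupling.items()]},
    )
    if roles:
        _emit_table(lines, "roles", dict(roles))
    if protocol is not None:
        _emit_table(
            lines,
            "protocol",
            {
                "windows": list(protocol.window_centers),
                "k_umb": protocol.k_umb,
                "n_steps": protocol.n_steps,
                "n_equil": protocol.n_equil,
                "sample_stride": protocol.sample_stride,
                "seed": protocol.seed_base,
                "bins": [protocol.bins[0], protocol.bins[1], int(protocol.bins[2])],
            },
        )
    if tiny is not None:
        _emit_table(
            lines,
            "tiny",
            {
                "h": tiny.h,
                "particles": [[t.name, lab] for t, lab in tiny.particles],
            },
        )
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# TOML reading with strict key validation

_ALLOWED = {
    "": {"schema_version", "box", "potential", "cv", "sites", "species", "coupling",
         "roles", "protocol", "tiny"},
    "box": {"dimension", "length", "periodic"},
    "potential": {"cutoff", "temperature"},
    "cv": {"kind", "species_a", "species_b", "site_a", "site_b"},
    "sites.*": {"epsilon", "sigma", "charge"},
    "species.*": {"sites", "count", "rigid", "geometry", "bonds"},
    "coupling": {"pairs"},
    "roles": {"solute_a", "solute_b", "solvent"},
    "protocol": {"windows", "k_umb", "n_steps", "n_equil", "sample_stride", "seed", "bins"},
    "tiny": {"h", "particles"},
}


def _check_keys(table: dict, allowed: set, where: str) -> None:
    for k in table:
        if k not in allowed:
            raise SchemaError(f"unknown key {where}.{k}" if where else f"unknown key {k}")


def read_config(path: str | Path) -> ConfigBundle:
    """Parse and validate a config file into system/protocol/roles objects."""
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    _check_keys(doc, _ALLOWED[""], "")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    for req in ("box", "potential", "sites", "species", "coupling"):
        if req not in doc:
            raise SchemaError(f"missing required table [{req}]")

    box = doc["box"]
    _check_keys(box, _ALLOWED["box"], "box")
    pot = doc["potential"]
    _check_keys(pot, _ALLOWED["potential"], "potential")

    sites: dict[str, SiteType] = {}
    for name, tbl in doc["sites"].items():
        _check_keys(tbl, _ALLOWED["sites.*"], f"sites.{name}")
        sites[name] = SiteType(
            name=name,
            lj_epsilon=float(tbl["epsilon"]),
            lj_sigma=float(tbl["sigma"]),
            charge=float(tbl.get("charge", 0.0)),
        )

    species: list[Species] = []
    for label, tbl in doc["species"].items():
        _check_keys(tbl, _ALLOWED["species.*"], f"species.{label}")
        try:
            site_list = tuple(sites[s] for s in tbl["sites"])
        except KeyError as e:
            raise SchemaError(f"species.{label}.sites references unknown site {e}") from None
        bonds = tuple(
            Bond(i=int(b[0]), j=int(b[1]), k=float(b[2]), r0=float(b[3]))
            for b in tbl.get("bonds", [])
        )
        tpl = MoleculeTemplate(
            sites=site_list,
            geometry=tuple(tuple(float(x) for x in g) for g in tbl["geometry"]),
            bonds=bonds,
            rigid=bool(tbl.get("rigid", False)),
        )
        species.append(Species(label=label, template=tpl, n_molecules=int(tbl["count"])))

    _check_keys(doc["coupling"], _ALLOWED["coupling"], "coupling")
    entries: dict[tuple[str, str], float] = {}
    for p in doc["coupling"]["pairs"]:
        if len(p) != 3:
            raise SchemaError(f"coupling.pairs entry {p!r} must be [a, b, lambda]")
        a, b, lam = str(p[0]), str(p[1]), float(p[2])
        key = (a, b) if a <= b else (b, a)
        if key in entries and entries[key] != lam:
            raise SchemaError(f"asymmetric coupling entries for pair {key}")
        entries[key] = lam
    coupling = CouplingMatrix(entries)

    cv = None
    if "cv" in doc:
        tbl = doc["cv"]
        _check_keys(tbl, _ALLOWED["cv"], "cv")
        cv = CVSpec(
            kind=str(tbl["kind"]),
            species_a=str(tbl["species_a"]),
            species_b=str(tbl["species_b"]),
            site_a=int(tbl.get("site_a", 0)),
            site_b=int(tbl.get("site_b", 0)),
        )

    system = SystemSpec(
        species=tuple(species),
        coupling=coupling,
        box_length=float(box["length"]),
        temperature=float(pot["temperature"]),
        cv=cv,
        periodic=bool(box.get("periodic", True)),
        cutoff=float(pot["cutoff"]),
        dimension=int(box["dimension"]),
    )

    protocol = None
    if "protocol" in doc:
        tbl = doc["protocol"]
        _check_keys(tbl, _ALLOWED["protocol"], "protocol")
        lo, hi, n = tbl["bins"]
        protocol = Protocol(
            window_centers=tuple(float(w) for w in tbl["windows"]),
            k_umb=float(tbl["k_umb"]),
            n_steps=int(tbl["n_steps"]),
            n_equil=int(tbl["n_equil"]),
            sample_stride=int(tbl["sample_stride"]),
            seed_base=int(tbl["seed"]),
            bins=(float(lo), float(hi), int(n)),
        )

    roles = {}
    if "roles" in doc:
        _check_keys(doc["roles"], _ALLOWED["roles"], "roles")
        roles = {k: str(v) for k, v in doc["roles"].items()}

    tiny = None
    if "tiny" in doc:
        tbl = doc["tiny"]
        _check_keys(tbl, _ALLOWED["tiny"], "tiny")
        particles = []
        for name, lab in tbl["particles"]:
            if name not in sites:
                raise SchemaError(f"tiny.particles references unknown site {name!r}")
            particles.append((sites[name], str(lab)))
        tiny = TinySystem(
            dimension=system.dimension,
            box_length=system.box_length,
            temperature=system.temperature,
            h=float(tbl["h"]),
            particles=tuple(particles),
            periodic=system.periodic,
            cutoff=system.cutoff,
        )

    return ConfigBundle(system=system, protocol=protocol, roles=roles, tiny=tiny)


def generate_fixture(name: str, n_v: int | None = None, seed: int = 0, out_dir=".") -> Path:
    """Write one named fixture as a config file; byte-identical per (name, seed)."""
    from .fixtures import make_fixture

    fx = make_fixture(name, n_v=n_v, seed=seed)
    roles = {"solute_a": fx.solute_a.label, "solute_b": fx.solute_b.label}
    if fx.solvent is not None:
        roles["solvent"] = fx.solvent.label
    out = Path(out_dir) / f"{name}.toml"
    out.parent.mkdir(parents=True, exist_ok=True)
    write_config(out, fx.system("FULL"), protocol=fx.protocol, roles=roles, tiny=fx.tiny)
    return out


# ---------------------------------------------------------------------------
# profiles


def write_profile(path: str | Path, profile: PMFProfile, meta: dict | None = None) -> Path:
    """TSV (r, F_kT, err_kT, n_samples) + JSON sidecar; lossless round-trip."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "r": profile.grid,
            "F_kT": profile.values,
            "err_kT": profile.errors,
            "n_samples": profile.n_samples,
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="nan", float_format="%.17g")
    sidecar = {
        "anchor": profile.anchor,
        "jacobian_corrected": profile.jacobian_corrected,
        "dimension": profile.dimension,
    }
    if meta:
        sidecar["meta"] = meta
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_profile(path: str | Path) -> PMFProfile:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"profile sidecar {sidecar_path} is missing")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path, sep="\t", na_values=["nan"], float_precision="round_trip")
    return PMFProfile(
        grid=df["r"].to_numpy(float),
        values=df["F_kT"].to_numpy(float),
        errors=df["err_kT"].to_numpy(float),
        n_samples=df["n_samples"].to_numpy(),
        anchor=sidecar["anchor"],
        jacobian_corrected=sidecar["jacobian_corrected"],
        dimension=sidecar["dimension"],
    )


# ---------------------------------------------------------------------------
# sample sets


def write_samples(path: str | Path, samples: SampleSet) -> Path:
    """TSV (step, cv, energy, bias_energy) + JSON sidecar with run metadata."""
    path = Path(path)
    step = samples.n_equil + samples.sample_stride * (1 + np.arange(samples.n_samples))
    df = pd.DataFrame(
        {
            "step": step,
            "cv": samples.cv_samples,
            "energy": samples.energy_samples,
            "bias_energy": samples.bias_energy_samples,
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="nan", float_format="%.17g")
    sidecar = {
        "seed": samples.seed,
        "system_digest": samples.system_digest,
        "acceptance_rate": samples.acceptance_rate,
        "n_steps": samples.n_steps,
        "n_equil": samples.n_equil,
        "sample_stride": samples.sample_stride,
        "temperature": samples.temperature,
        "dimension": samples.dimension,
        "bias": {"kind": samples.bias.kind, "k_umb": samples.bias.k_umb, "r0": samples.bias.r0},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_samples(path: str | Path) -> SampleSet:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sample sidecar {sidecar_path} is missing")
    sc = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return SampleSet(
        cv_samples=df["cv"].to_numpy(float),
        energy_samples=df["energy"].to_numpy(float),
        bias_energy_samples=df["bias_energy"].to_numpy(float),
        bias=BiasSpec(**sc["bias"]),
        n_steps=sc["n_steps"],
        n_equil=sc["n_equil"],
        sample_stride=sc["sample_stride"],
        seed=sc["seed"],
        acceptance_rate=sc["acceptance_rate"],
        temperature=sc["temperature"],
        dimension=sc["dimension"],
        system_digest=sc["system_digest"],
    )


# ---------------------------------------------------------------------------
# extended XYZ configurations


def write_xyz(path: str | Path, cfg: Configuration, system: SystemSpec) -> Path:
    """Extended XYZ; coordinates padded to 3 columns, box in the comment line."""
    from .model import EnergyModel

    path = Path(path)
    model = EnergyModel(system)
    pos = cfg.positions
    n, d = pos.shape
    pad = np.zeros((n, 3))
    pad[:, :d] = pos
    L = system.box_length
    lattice = " ".join(
        str(x) for x in [L, 0, 0, 0, L, 0, 0, 0, L]
    )
    labels = [model.species_labels[s] for s in model.site_species]
    lines = [str(n)]
    lines.append(
        f'Lattice="{lattice}" Properties=species:S:1:pos:R:3'
        f" dimension={d} periodic={'T' if system.periodic else 'F'}"
    )
    for lab, row in zip(labels, pad):
        lines.append(f"{lab} {row[0]:.17g} {row[1]:.17g} {row[2]:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_xyz(path: str | Path) -> tuple[np.ndarray, list[str], int]:
    """Read an extended XYZ file -> (positions (n, dim), labels, dimension)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    n = int(lines[0])
    comment = lines[1]
    dim = 3
    for tok in comment.split():
        if tok.startswith("dimension="):
            dim = int(tok.split("=", 1)[1])
    labels, rows = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:4]])
    pos = np.asarray(rows)[:, :dim]
    return pos, labels, dim


# ---------------------------------------------------------------------------
# run manifests


def write_manifest(
    path: str | Path,
    config_path: str | Path | None,
    seeds: list[int],
    outputs: list[str],
    extra: dict | None = None,
) -> Path:
    """JSON run manifest: config digest, seeds, version, timestamps, outputs."""
    path = Path(path)
    digest = None
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]
    doc = {
        "tool": "pcmc",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config_digest": digest,
        "seeds": seeds,
        "outputs": outputs,
    }
    if extra:
        doc.update(extra)
    path.write_text(json.dumps(doc, indent=1))
    return path
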