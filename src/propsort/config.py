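"""Named parameter profiles and profile-file loading.

``table1_mea`` and ``table1_np`` are the shipped device profiles.  A custom
profile is a JSON file holding a sampling rate plus every field of
:class:`~propsort.params.Params` under its snake_case name; unknown keys are
rejected and missing keys are reported by name so a profile file is always a
complete, auditable record of a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .params import Params, mea_params, neuropixels_params

__all__ = ["Profile", "load_profile"]


@dataclass(frozen=True)
class Profile:
    name: str
    sampling_rate: float  # Hz the detector of this profile expects
    params: Params


_BUILTIN = {
    "table1_mea": lambda: Profile("table1_mea", 20000.0, mea_params()),
    "table1_np": lambda: Profile("table1_np", 30000.0, neuropixels_params()),
}


def load_profile(name_or_path: str | Path) -> Profile:
    """Load a built-in profile by name or a custom profile from a JSON file."""
    key = str(name_or_path)
    if key in _BUILTIN:
        return _BUILTIN[key]()
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"unknown profile {key!r}; expected one of "
            f"{sorted(_BUILTIN)} or a readable JSON file"
        )
    doc = json.loads(path.read_text())
    if "sampling_rate_hz" not in doc:
        raise ValueError("profile file is missing 'sampling_rate_hz'")
    field_names = {f.name for f in dataclasses.fields(Params)}
    body = {k: v for k, v in doc.items() if k not in ("sampling_rate_hz", "name")}
    unknown = set(body) - field_names
    if unknown:
        raise ValueError(f"unknown profile keys: {sorted(unknown)}")
    missing = field_names - set(body)
    if missing:
        raise ValueError(f"profile file is missing: {sorted(missing)}")
    return Profile(
        name=doc.get("name", path.stem),
        sampling_rate=float(doc["sampling_rate_hz"]),
        params=Params(**body),
    )
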