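"""Text interchange format for SWAXS profiles.

Profiles travel as 2- or 3-column whitespace-delimited text
(q [1/A], I(q), optional sigma), with '#'-prefixed comment/header lines.
Writing uses 17 significant digits, so a write -> read round trip is exact
at the formatted precision.  Parse failures report the offending line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .scattering import QGrid, ScatteringProfile


class ProfileParseError(ValueError):
    pass


def read_profile(path: str | Path) -> ScatteringProfile:
    """Read a profile file; sigma is optional and may be absent."""
    path = Path(path)
    q, intensity, sigma = [], [], []
    n_cols = None
    meta = {"conformation_id": "", "condition": "experimental"}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for key in meta:
                prefix = f"# {key}:"
                if line.startswith(prefix):
                    meta[key] = line[len(prefix):].strip()
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ProfileParseError(
                f"{path.name}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
            )
        if n_cols is None:
            n_cols = len(parts)
        elif len(parts) != n_cols:
            raise ProfileParseError(
                f"{path.name}:{lineno}: inconsistent column count"
            )
        try:
            values = [float(p) for p in parts]
        except ValueError:
            raise ProfileParseError(
                f"{path.name}:{lineno}: non-numeric value"
            ) from None
        if any(np.isnan(values)):
            raise ProfileParseError(f"{path.name}:{lineno}: NaN value")
        if q and values[0] <= q[-1]:
            raise ProfileParseError(
                f"{path.name}:{lineno}: q values must be strictly increasing"
            )
        if n_cols == 3 and values[2] < 0:
            raise ProfileParseError(f"{path.name}:{lineno}: negative sigma")
        q.append(values[0])
        intensity.append(values[1])
        if n_cols == 3:
            sigma.append(values[2])
    if len(q) < 2:
        raise ProfileParseError(f"{path.name}: fewer than 2 data lines")
    return ScatteringProfile(
        qgrid=QGrid(np.array(q)),
        intensity=np.array(intensity),
        sigma=np.array(sigma) if sigma else None,
        conformation_id=meta["conformation_id"],
        condition=meta["condition"],
    )


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "# q[1/A]  I(q)" + ("  sigma" if profile.sigma is not None else ""),
        f"# conformation_id: {profile.conformation_id}",
        f"# condition: {profile.condition}",
    ]
    for j, (qj, ij) in enumerate(zip(profile.q, profile.intensity)):
        cols = [f"{qj:.17g}", f"{ij:.17g}"]
        if profile.sigma is not None:
            cols.append(f"{profile.sigma[j]:.17g}")
        lines.append("  ".join(cols))
    path.write_text("\n".join(lines) + "\n")
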