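"""Flat sectioned key=value configuration with the processing defaults.

One defaults table holds every pipeline parameter: peak-search thresholds
for both passes (700 / 200 / 150 ADU), signal-to-noise cuts (5 / 3),
squared-gradient cut (10,000), median filter window (16 px), the 10 px
subtraction radius, integration radii (6, 6, 8), and the loose cell
restraints (10% lengths, 2% angles).
"""

from __future__ import annotations

DEFAULTS: dict[str, dict[str, float]] = {
    "threshold_estimation": {
        # tau = median over images of (mu + 4 sigma); the heavy-tailed
        # (Cauchy) reading of that rule puts tau at the 0.92 quantile
        "n_images": 1000,
        "sigma_multiplier": 4,
    },
    "peaks_pass1": {
        "threshold": 700,       # ADU
        "min_snr": 5,
        "min_gradient": 10000,  # squared gradient, ADU^2/px^2
        "median_window": 16,    # px
        "peak_max_diameter": 10,
    },
    "peaks_pass2": {
        "threshold": 150,       # ADU, lowered to pick up the weak colour
        "min_snr": 3,
        "min_gradient": 10000,
        "median_window": 16,
        "peak_max_diameter": 10,
    },
    "indexing": {
        "max_length_deviation": 0.10,  # loose cell imposition
        "max_angle_deviation": 0.02,
        "quorum": 10,
        "match_radius": 4.0,     # px, peak <-> prediction assignment
        "accept_fraction": 0.4,  # fraction of peaks a solution must explain
        "subtract_radius": 10.0,  # px, removal around the first pattern
    },
    "integration": {
        "radius_peak": 6,
        "radius_bg_inner": 6,
        "radius_bg_outer": 8,
    },
    "hit_finding": {
        "min_peaks": 15,
    },
}


def format_config(cfg: dict | None = None) -> str:
    cfg = cfg if cfg is not None else DEFAULTS
    lines = []
    for section, values in cfg.items():
        lines.append(f"[{section}]")
        for key, val in values.items():
            lines.append(f"{key} = {val}")
        lines.append("")
    return "\n".join(lines)


def write_config(path, cfg: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(format_config(cfg))


def read_config(path) -> dict:
    out: dict[str, dict[str, float]] = {}
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].split(";")[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                out[section] = {}
                continue
            if section is None:
                raise ValueError(f"key outside a [section]: {raw!r}")
            key, _, val = line.partition("=")
            v = val.strip()
            try:
                parsed: float | str = int(v)
            except ValueError:
                try:
                    parsed = float(v)
                except ValueError:
                    parsed = v
            out[section][key.strip()] = parsed
    return out


def merged_config(path=None, overrides: dict | None = None) -> dict:
    """DEFAULTS, updated by an optional file, updated by overrides."""
    cfg = {s: dict(v) for s, v in DEFAULTS.items()}
    if path is not None:
        for s, v in read_config(path).items():
            cfg.setdefault(s, {}).update(v)
    for key, val in (overrides or {}).items():
        section, _, name = key.partition(".")
        cfg.setdefault(section, {})[name] = val
    return cfg
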