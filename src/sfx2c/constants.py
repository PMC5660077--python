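"""Physical constants and small lookup tables used across the package."""

import numpy as np

# Product h*c expressed in keV * Angstrom. Single package-wide value; every
# energy <-> wavelength conversion goes through this constant.
HC_KEV_ANGSTROM = 12.3984

# Silicon lattice constant (diamond cubic), Angstrom. Used to assign
# d-spacings to powder calibration rings.
SI_LATTICE_A = 5.431

# Approximate atomic numbers used as flat normal scattering factors f0 for
# the toy structure-factor simulator (no s-dependence).
F0_BY_ELEMENT = {"C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0, "Gd": 64.0}


def si_powder_d_spacings(n: int = 5) -> np.ndarray:
    """Return the `n` largest d-spacings of the silicon powder pattern.

    Diamond-cubic reflection conditions: h, k, l all odd, or all even with
    h + k + l divisible by 4.
    """
    seen = set()
    rng = range(0, 9)
    for h in rng:
        for k in rng:
            for l in rng:
                if h == k == l == 0:
                    continue
                odd = h % 2 == 1 and k % 2 == 1 and l % 2 == 1
                even = (
                    h % 2 == 0 and k % 2 == 0 and l % 2 == 0
                    and (h + k + l) % 4 == 0
                )
                if odd or even:
                    seen.add(h * h + k * k + l * l)
    d = SI_LATTICE_A / np.sqrt(np.array(sorted(seen), dtype=float))
    return np.sort(d)[::-1][:n]
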