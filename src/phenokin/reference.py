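"""Published Haldane parameter sets for phenol-degrading microbes.

A small literature table of fitted (rate*, Ks, Ki) triples, with the Sm and
true-maximum values the original reports printed, useful both as a
comparison baseline for new fits and as a cross-check that the closed-form
derivations reproduce what the literature reports.  Entries with missing
cells carry ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .kinetics import HaldaneParameters, critical_substrate, true_max_rate

__all__ = ["LiteratureEntry", "GROWTH_LITERATURE", "DEGRADATION_LITERATURE", "literature_table"]


@dataclass(frozen=True)
class LiteratureEntry:
    organism: str
    rate_star: float | None  # h^-1 (mu* or q*)
    ks: float | None  # mg/L
    ki: float | None  # mg/L
    s_m_reported: float | None  # mg/L
    true_max_reported: float | None  # h^-1
    r2_reported: float | None

    @property
    def params(self) -> HaldaneParameters | None:
        if None in (self.rate_star, self.ks, self.ki):
            return None
        return HaldaneParameters(rate_star=self.rate_star, ks=self.ks, ki=self.ki)


#: Growth-branch (mu) literature values for cells grown on phenol.
GROWTH_LITERATURE: tuple[LiteratureEntry, ...] = (
    LiteratureEntry("G. nicotianae MSSRFPD35", 0.574, 20.29, 268.1, 73.76, 0.37, 0.98),
    LiteratureEntry("P. putida LY1", 0.217, 24.40, 121.70, 54.50, 0.114, 0.96),
    LiteratureEntry("P. putida MTCC 1194", 0.109, 53.20, 148.60, 88.90, 0.050, 0.91),
    LiteratureEntry("Alcaligenes sp. TW1", 0.58, 10.00, 550.00, 74.20, 0.457, None),
    LiteratureEntry("A. faecalis B6-2", 0.48, 469.23, 188.16, 297.10, 0.12, 0.90),
    LiteratureEntry("A. johnsonii D1", 0.55, 483.83, 2582.63, 1117.80, 0.29, 0.96),
    LiteratureEntry("B. brevis", 0.078, 29.31, 2434.70, 267.10, 0.064, 0.95),
    LiteratureEntry("S. solfataricus 98/2", 0.094, 77.70, 319.40, 157.50, 0.047, 0.95),
    LiteratureEntry("B. cereus MTCC 9817", 0.4396, 129.40, 637.80, 287.28, 0.2312, 0.81),
    LiteratureEntry("Gulosibacter sp. YZ4", 0.601, 70.87, 418.20, None, None, 0.98),
    LiteratureEntry("P. variotii JH6", 0.312, 130.40, 200.00, 161.493, 0.11931, 0.95),
    LiteratureEntry("C. tropicalis PHB5", 0.3407, 15.81, 169.00, 51.69, 0.2113, 0.99),
)

#: Degradation-branch (q) literature values.
DEGRADATION_LITERATURE: tuple[LiteratureEntry, ...] = (
    LiteratureEntry("G. nicotianae MSSRFPD35", 1.244, 9.152, 517.5, 68.820, 0.983, 0.7542),
    LiteratureEntry("B. cereus MTCC 9817", 27.85, 59150.0, 2.411, 377.63, 0.089, 0.64),
    LiteratureEntry("B. cereus MTCC 9818", 1.635, 9.706, 3873.00, 193.88, 1.486, 0.82),
    LiteratureEntry("S. maltophilia CUPS-3", 58.80, 1688.00, 0.868, 38.27, 0.659, 0.84),
    LiteratureEntry("Pseudomonas sp. CUPS-2", 34.39, 850.50, 0.878, 27.32, 0.544, 0.98),
    LiteratureEntry("P. aeruginosa CUPS-5", 14.31, 252.60, 2.468, 24.96, 0.674, 0.94),
    LiteratureEntry("S. solfataricus 98/2", None, 130.30, 291.10, 174.9, 0.110, 0.93),
    LiteratureEntry("C. tropicalis PHB5", 0.2766, 2.819, 2093.00, 76.81, 0.257, 0.82),
)


def literature_table(branch: str = "growth") -> pd.DataFrame:
    """Literature triples with Sm and the true maximum recomputed closed-form.

    Rows lacking a complete (rate*, Ks, Ki) triple keep NaN in the
    recomputed columns.
    """
    entries = GROWTH_LITERATURE if branch == "growth" else DEGRADATION_LITERATURE
    rows = []
    for e in entries:
        p = e.params
        rows.append(
            {
                "organism": e.organism,
                "rate_star": e.rate_star,
                "ks": e.ks,
                "ki": e.ki,
                "s_m_reported": e.s_m_reported,
                "true_max_reported": e.true_max_reported,
                "s_m": critical_substrate(p) if p else float("nan"),
                "true_max": true_max_rate(p) if p else float("nan"),
                "r2_reported": e.r2_reported,
            }
        )
    return pd.DataFrame(rows)
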