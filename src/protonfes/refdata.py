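"""Literature reference free energies for G-T mispair tautomerization.

Reaction free energies ΔA, forward barriers ΔAf‡ and reverse barriers ΔAr‡
(kcal/mol, 298 K) for the three tautomerization steps of the guanine-
thymine mispair in B-DNA, as reported for several levels of theory:
an experimentally derived estimate (NMR rates through transition-state
theory with unit transmission coefficient), ab initio QM/MM
(PBE0/6-31G*), semiempirical QM/MM (AM1/d), a Δ-machine-learning-corrected
QM/MM model, and path-integral MD with the corrected model.  Parenthesized
standard errors in the source (SEM over 4 independent trials) are stored
alongside; ``None`` marks values not reported.

These numbers are *inputs* for the worked examples of the kinetics module
(TST rate factors, population ratios, method-comparison tables); nothing in
this package recomputes them.
"""

from __future__ import annotations

REACTIONS = ("wGT->GT*", "wGT->G*T", "GT*->G*T")
METHODS = ("experiment", "PBE0/6-31G*", "AM1/d", "QM/MM-dMLP", "PIMD")

#: reaction -> method -> {dA, dA_err, dAf, dAf_err, dAr, dAr_err}
TAUTOMER_FREE_ENERGIES: dict[str, dict[str, dict[str, float | None]]] = {
    "wGT->GT*": {
        "experiment": {"dA": 4.43, "dA_err": None, "dAf": 16.88, "dAf_err": None,
                       "dAr": 12.45, "dAr_err": None},
        "PBE0/6-31G*": {"dA": 3.97, "dA_err": 0.04, "dAf": 20.41, "dAf_err": 0.05,
                        "dAr": 16.45, "dAr_err": 0.04},
        "AM1/d": {"dA": 9.54, "dA_err": 0.04, "dAf": 23.51, "dAf_err": 0.06,
                  "dAr": 13.98, "dAr_err": 0.05},
        "QM/MM-dMLP": {"dA": 3.67, "dA_err": 0.07, "dAf": 21.01, "dAf_err": 0.07,
                       "dAr": 17.34, "dAr_err": 0.07},
        "PIMD": {"dA": 3.48, "dA_err": 0.03, "dAf": 20.65, "dAf_err": 0.04,
                 "dAr": 17.16, "dAr_err": 0.03},
    },
    "wGT->G*T": {
        "experiment": {"dA": 3.82, "dA_err": None, "dAf": None, "dAf_err": None,
                       "dAr": None, "dAr_err": None},
        "PBE0/6-31G*": {"dA": 3.06, "dA_err": 0.04, "dAf": 20.08, "dAf_err": 0.05,
                        "dAr": 17.02, "dAr_err": 0.05},
        "AM1/d": {"dA": 8.19, "dA_err": 0.04, "dAf": 23.55, "dAf_err": 0.04,
                  "dAr": 15.36, "dAr_err": 0.04},
        "QM/MM-dMLP": {"dA": 3.24, "dA_err": 0.07, "dAf": 21.02, "dAf_err": 0.07,
                       "dAr": 17.78, "dAr_err": 0.07},
        "PIMD": {"dA": 3.75, "dA_err": 0.04, "dAf": 20.63, "dAf_err": 0.04,
                 "dAr": 16.88, "dAr_err": 0.04},
    },
    "GT*->G*T": {
        "experiment": {"dA": -0.62, "dA_err": None, "dAf": 9.21, "dAf_err": None,
                       "dAr": 9.83, "dAr_err": None},
        "PBE0/6-31G*": {"dA": -0.91, "dA_err": 0.03, "dAf": 6.72, "dAf_err": 0.05,
                        "dAr": 7.63, "dAr_err": 0.05},
        "AM1/d": {"dA": -1.36, "dA_err": 0.03, "dAf": 10.26, "dAf_err": 0.03,
                  "dAr": 11.62, "dAr_err": 0.04},
        "QM/MM-dMLP": {"dA": -0.43, "dA_err": 0.07, "dAf": 7.06, "dAf_err": 0.07,
                       "dAr": 7.49, "dAr_err": 0.07},
        "PIMD": {"dA": 0.26, "dA_err": 0.03, "dAf": 4.21, "dAf_err": 0.03,
                 "dAr": 3.95, "dAr_err": 0.04},
    },
}
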