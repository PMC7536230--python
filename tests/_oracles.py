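"""Independent oracles shared by the unit and acceptance suites."""

import numpy as np

GAMMA, B, MU = 0.0067, 2.0, 0.00026


def literal_derivatives_oracle(model, m, R, sensor):
    """Term-by-term transcription of the published equation set.

    Wiring, read-through and loss terms are written out explicitly,
    independently of the CircuitModel implementation.
    """
    cfg = model.config
    pscale = cfg["scales"]["promoter"]
    kscale = cfg["scales"]["binding_constant"]
    gates = {g["name"]: g for g in cfg["gates"]}
    gi = {name: i for i, name in enumerate(model.gate_names)}

    def y(prom, gate_name):
        p = cfg["promoters"][prom]
        rep = cfg["repressors"][prom]
        ymax = p["y_max"] * pscale * p["copies"]
        ymin = p["y_min"] * pscale * p["copies"]
        k = rep["k"] * kscale
        n = rep["n"]
        Ri = R[gi[gate_name]]
        return ymin + (ymax - ymin) * k**n / (k**n + Ri**n)

    T = cfg["terminators"]
    eta = cfg["ribozymes"]
    rbs = cfg["rbs"]

    J = {}
    J["phlF"] = y("P_SrpR", "srpR") + y("P_BetI", "betI")
    J["srpR"] = sensor["P_BAD1"] + sensor["P_Tet1"] + J["phlF"] / T["ECK120033737"]
    J["bm3R1"] = (
        y("P_PhlF", "phlF") + y("P_HlyIIR", "hlyIIR") + J["srpR"] / T["ECK120029600"]
    )
    J["betI"] = y("P_AmtR", "amtR") + y("P_AmeR", "ameR") + J["bm3R1"] / T["L3S2P11"]
    J["ameR"] = sensor["P_Tet2"] + J["betI"] / T["L3S3P11"]
    J["hlyIIR"] = sensor["P_Tac"] + J["ameR"] / T["L3S3P31"]
    J["amtR"] = sensor["P_BAD2"] + J["hlyIIR"] / T["ECK120033736"]
    J["yfp"] = y("P_BM3R1", "bm3R1")

    rz = {name: gates[name]["ribozyme"] for name in gates}
    al = {name: rbs[gates[name]["rbs"]] for name in gates}
    dm = np.array(
        [
            J[name] - GAMMA * (eta[rz[name]] * (1 - B) + B) * m[gi[name]]
            for name in model.gate_names
        ]
    )
    dR = np.array(
        [al[name] * m[gi[name]] - MU * R[gi[name]] for name in model.gate_names]
    )
    return dm, dR
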