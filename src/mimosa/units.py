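"""Centralized unit conversions.

Internal conventions used everywhere in the package:

==================  =========================
concentration       uM (umol per litre)
grid length         um
time step           h
flux                mmol per gDW per h
amount              mmol
mass                g (dry weight)
diffusivity         um^2 per s
light               uE
==================  =========================
"""

SECONDS_PER_HOUR = 3600.0

#: litres in one cubic micrometre
L_PER_UM3 = 1e-15

#: toy-network biomass "molar mass" (g per mmol); chosen so that a biomass
#: flux in mmol/gDW/h is numerically the specific growth rate in 1/h.
BIOMASS_G_PER_MMOL = 1.0


def hours_to_seconds(dt_h: float) -> float:
    return dt_h * SECONDS_PER_HOUR


def gridcell_volume_L(delta_um: float) -> float:
    """Volume of one cubic gridcell (edge ``delta_um``) in litres."""
    return delta_um**3 * L_PER_UM3


def conc_to_amount_mmol(conc_uM: float, delta_um: float) -> float:
    """uM concentration in one gridcell -> absolute amount in mmol."""
    return conc_uM * gridcell_volume_L(delta_um) * 1e-3


def amount_to_conc_uM(amount_mmol: float, delta_um: float) -> float:
    """Absolute amount in mmol spread over one gridcell -> uM."""
    return amount_mmol * 1e3 / gridcell_volume_L(delta_um)


def amount_to_flux(amount_mmol: float, mass_g: float, dt_h: float) -> float:
    """Amount consumable over one time step -> flux bound (mmol/gDW/h)."""
    return amount_mmol / (mass_g * dt_h)


def flux_to_amount(flux: float, mass_g: float, dt_h: float) -> float:
    """Flux sustained over one time step -> absolute amount in mmol."""
    return flux * mass_g * dt_h
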