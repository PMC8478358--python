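# Default coefficient registry: the published calibrations used in "printed" mode.
# Every power law is y = base^(slope * log_base(x) + intercept).
power_laws:
  brain_mass_from_endocranial_volume:
    slope: 0.933
    intercept: 0.088
    base: 10
    x_unit: cm3
    y_unit: g
    note: >
      PGLS calibration on extant placental species means (26 species, 18 genera);
      adjusted R2 0.991, lambda effectively 0.
  body_mass_from_ocw:
    slope: 3.135
    intercept: -3.575
    base: 10
    x_unit: mm
    y_unit: kg
    note: >
      PGLS calibration on adult extant cetacean species means (27 species,
      8 families, 74 adult specimens); adjusted R2 0.87, lambda 0.942.
  # The earlier-literature OCW law used for back-calculating OCW from published
  # body masses is attributed but not printed in the source study; supply it via
  # a user registry if needed.  It is deliberately absent here.

densities:
  # Specific density of brain tissue, g/cm3, selected by group label.
  cetacean: 1.04
  terrestrial: 1.036

eq_scalings:
  artiodactyl:
    label: EQ_0.56
    exponent: 0.56
    constant: 0.44
  all_mammal:
    label: EQ_0.75
    exponent: 0.75
    constant: 1.26

# Fixed volumetric deduction (fraction of endocranial volume) applied to
# basilosaurids in earlier literature for the cranial rete; OFF by default
# because the present analysis argues against a fixed correction.
rete_correction_fraction: 0.20
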