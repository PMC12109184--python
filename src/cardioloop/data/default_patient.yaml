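# Default (healthy reference) closed-loop parameter set.
#
# Single source of truth for the packaged fixtures: the healthy patient is
# built verbatim from this file, and the cardiogenic-shock patient is derived
# from it by the deterministic tuner (Ees scale, blood volume, systemic
# resistance scale).  Units: mmHg, mL, s.  Values are stand-ins assembled
# from standard 0D-model literature ranges and calibrated once so the
# healthy simulation lands in the documented sanity band (CO 4.5-6 L/min,
# mean aortic pressure 85-100 mmHg at HR 70); no published per-segment
# parameter table exists for the study this model emulates.

heart_rate: 70.0          # bpm
bsa: 1.8                  # m^2
total_blood_volume: 5550.0  # mL, distributed across segments at init

chambers:
  # ees mmHg/mL, v0 mL, EDPVR P = a*(exp(b*(V-v0))-1)
  LV: {ees: 2.50, v0: 10.0, edpvr_a: 0.55, edpvr_b: 0.025}
  RV: {ees: 0.65, v0: 10.0, edpvr_a: 0.35, edpvr_b: 0.022}
  LA: {ees: 0.45, v0: 5.0,  edpvr_a: 0.50, edpvr_b: 0.035}
  RA: {ees: 0.35, v0: 5.0,  edpvr_a: 0.40, edpvr_b: 0.035}

septum:
  k_sept: 0.02            # mmHg/mL, pressure superposition coupling
  v_lv_ref: 100.0
  v_rv_ref: 100.0

valves:
  # diode + series resistance; regularization width smooths the corner
  mitral:    {resistance: 0.005, regularization: 0.1}
  aortic:    {resistance: 0.006, regularization: 0.1}
  tricuspid: {resistance: 0.004, regularization: 0.1}
  pulmonic:  {resistance: 0.005, regularization: 0.1}

nodes:
  # compliance mL/mmHg, unstressed_volume mL, init_pressure mmHg
  ascending_aorta:     {compliance: 0.42, unstressed_volume: 60.0,   init_pressure: 80.0}
  aortic_arch:         {compliance: 0.30, unstressed_volume: 40.0,   init_pressure: 80.0}
  thoracic_aorta:      {compliance: 0.30, unstressed_volume: 60.0,   init_pressure: 79.0}
  descending_aorta:    {compliance: 0.375, unstressed_volume: 80.0,   init_pressure: 78.0}
  abdominal_aorta:     {compliance: 0.30, unstressed_volume: 70.0,   init_pressure: 77.0}
  femoral_artery:      {compliance: 0.225, unstressed_volume: 50.0,   init_pressure: 76.0}
  upper_body:          {compliance: 1.50, unstressed_volume: 300.0,  init_pressure: 25.0}
  renal_hepatic:       {compliance: 1.20, unstressed_volume: 300.0,  init_pressure: 25.0}
  splanchnic:          {compliance: 1.80, unstressed_volume: 600.0,  init_pressure: 25.0}
  lower_body:          {compliance: 1.00, unstressed_volume: 250.0,  init_pressure: 25.0}
  femoral_vein:        {compliance: 10.0, unstressed_volume: 250.0,  init_pressure: 6.0}
  inferior_vena_cava:  {compliance: 60.0, unstressed_volume: 1100.0, init_pressure: 4.5}
  superior_vena_cava:  {compliance: 25.0, unstressed_volume: 500.0,  init_pressure: 4.5}
  coronary:            {compliance: 0.12, unstressed_volume: 20.0,   init_pressure: 60.0}
  pulmonary_artery:    {compliance: 3.80, unstressed_volume: 100.0,  init_pressure: 15.0}
  pulmonary_veins:     {compliance: 15.0, unstressed_volume: 350.0,  init_pressure: 9.0}

links:
  # resistance mmHg*s/mL, inertance mmHg*s^2/mL
  # aortic chain (inertant); thoracic resistance sits on ta -> da
  aorta_to_arch:        {source: ascending_aorta,    target: aortic_arch,        resistance: 0.015, inertance: 0.0002}
  arch_to_thoracic:     {source: aortic_arch,        target: thoracic_aorta,     resistance: 0.015, inertance: 0.0002}
  thoracic_to_descending: {source: thoracic_aorta,   target: descending_aorta,   resistance: 0.020, inertance: 0.0003}
  descending_to_abdominal: {source: descending_aorta, target: abdominal_aorta,   resistance: 0.030, inertance: 0.0003}
  abdominal_to_femoral: {source: abdominal_aorta,    target: femoral_artery,     resistance: 0.050, inertance: 0.0004}
  # perfusion branches (proximal resistance dominant) and venous return
  arch_to_upper_body:   {source: aortic_arch,        target: upper_body,         resistance: 3.90}
  upper_body_to_svc:    {source: upper_body,         target: superior_vena_cava, resistance: 0.30}
  svc_to_ra:            {source: superior_vena_cava, target: RA,                 resistance: 0.12}
  aorta_to_coronary:    {source: ascending_aorta,    target: coronary,           resistance: 19.0}
  coronary_to_ra:       {source: coronary,           target: RA,                 resistance: 2.50}
  abdominal_to_renal:   {source: abdominal_aorta,    target: renal_hepatic,      resistance: 3.20}
  renal_to_ivc:         {source: renal_hepatic,      target: inferior_vena_cava, resistance: 0.30}
  abdominal_to_splanchnic: {source: abdominal_aorta, target: splanchnic,         resistance: 3.90}
  splanchnic_to_ivc:    {source: splanchnic,         target: inferior_vena_cava, resistance: 0.35}
  femoral_to_lower_body: {source: femoral_artery,    target: lower_body,         resistance: 6.30}
  lower_body_to_fv:     {source: lower_body,         target: femoral_vein,       resistance: 0.60}
  fv_to_ivc:            {source: femoral_vein,       target: inferior_vena_cava, resistance: 0.30}
  ivc_to_ra:            {source: inferior_vena_cava, target: RA,                 resistance: 0.12}
  # pulmonary circulation
  pa_to_pv:             {source: pulmonary_artery,   target: pulmonary_veins,    resistance: 0.050}
  pv_to_la:             {source: pulmonary_veins,    target: LA,                 resistance: 0.16}

initial_chamber_volumes:
  LV: 120.0
  RV: 120.0
  LA: 50.0
  RA: 50.0
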