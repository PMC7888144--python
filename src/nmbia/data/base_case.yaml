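# Base case: annual Spanish surgical procedure volumes (2015), published
# clinical mix, and 2019-euro per-administration drug and event costs.
# Adoption is given as the published annual sugammadex procedure counts;
# the clinical cost offset is the published calibrated value per procedure.
volumes:
  entries:
    - {category: Appendectomies, annual_count: 44593}
    - {category: Hernia repairs, annual_count: 70618}
    - {category: Cholecystectomies, annual_count: 72483}
    - {category: Colorectal resections, annual_count: 82435}
    - {category: Gastric surgeries, annual_count: 123401}
    - {category: Intracranial surgeries, annual_count: 20411}
    - {category: Spinal cord surgeries, annual_count: 49069}
    - {category: Femur surgeries, annual_count: 21415}
    - {category: Hip fracture repairs, annual_count: 42120}
    - {category: Knee fracture repairs, annual_count: 52493}
    - {category: Bronchoscopies/laryngoscopies, annual_count: 21599}
    - {category: Vocal cord surgeries, annual_count: 25673}
    - {category: Thyroid gland surgeries, annual_count: 21945}
    - {category: Prostatectomies, annual_count: 31332}
    - {category: Hysterectomies and oophorectomies, annual_count: 54289}
population:
  p_nmba: 0.733
  p_moderate: 0.80
  p_deep: 0.20
mix:
  p_no_reversal: 0.68
  p_neostigmine: 0.32
  agents_no_reversal: {rocuronium: 0.64, cisatracurium: 0.25, other: 0.11}
  agents_neostigmine: {rocuronium: 0.435, cisatracurium: 0.25, other: 0.315}
  p_switch_cisatracurium: 0.50
adoption:
  mode: direct_counts
  counts:
    moderate/no_reversal: 118034
    moderate/neostigmine: 81321
    deep/no_reversal: 29508
  # The published neostigmine-row count exceeds the eligible count implied by
  # the published mix; keep the published calibration and warn instead of fail.
  allow_count_overrun: true
drugs:
  rocuronium: 1.80
  neostigmine_atropine: 0.46
  sugammadex_moderate: 51.34
  sugammadex_deep: 102.68
events:
  atelectasis: {risk_no_sugammadex: 0.073, risk_sugammadex: 0.011, unit_cost: 4999.40}
  pneumonia: {risk_no_sugammadex: 0.040, risk_sugammadex: 0.019, unit_cost: 4449.72}
  offset_mode: calibrated
  calibrated_offset: 307.61
currency_rounding: 2
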