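# Default cost-parameter fixture (USD per patient per year).
# mean_annual_cost: average annual direct medical spending per patient with
# the disease; distribution: uncertainty spec used by the probabilistic
# sensitivity analysis (gamma: mean + standard error; uniform: bounds 20%
# away from the mean unless pct overrides).
delta_mn:
  value: 0.5
  distribution:
    uniform:
      pct: 0.2
  per_disease: {}
diseases:
  stroke:
    mean_annual_cost: 15000
    distribution:
      gamma:
        se: 1500
  copd:
    mean_annual_cost: 9800
    distribution:
      gamma:
        se: 1000
  chf:
    mean_annual_cost: 12000
    distribution:
      gamma:
        se: 1200
  colorectal_cancer:
    mean_annual_cost: 14000
    distribution:
      uniform:
        pct: 0.2
  breast_cancer:
    mean_annual_cost: 12000
    distribution:
      uniform:
        pct: 0.2
  dementia:
    mean_annual_cost: 36397
    distribution:
      gamma:
        se: 3640
  musculoskeletal:
    mean_annual_cost: 8000
    distribution:
      uniform:
        pct: 0.2
  depression:
    mean_annual_cost: 5000
    distribution:
      gamma:
        se: 500
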