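{
  "initial_profit": {"dist": "uniform", "low": 0.0, "high": 200.0},
  "initial_residents": {"dist": "loguniform", "low": 16.0, "high": 25.0},
  "initial_expiring_stock": {"dist": "loguniform", "low": 240.0, "high": 375.0},
  "initial_disposed_total": {"dist": "uniform", "low": 0.0, "high": 10.0},
  "initial_inventory_high": {"dist": "loguniform", "low": 720.0, "high": 1125.0},
  "workforce_competence": {"dist": "uniform", "low": 0.8, "high": 1.25},
  "pharmacists_in_team": {"dist": "uniform", "low": 1.6, "high": 2.5},
  "response_speed_base": {"dist": "uniform", "low": 0.53, "high": 0.83},
  "accuracy_adjust_time": {"dist": "loguniform", "low": 1.2, "high": 1.875},
  "avg_price_low": {"dist": "loguniform", "low": 8.0, "high": 12.5},
  "profit_margin_low": {"dist": "uniform", "low": 0.2, "high": 0.3125},
  "profit_margin_high": {"dist": "uniform", "low": 0.12, "high": 0.1875},
  "disposal_unit_cost": {"dist": "loguniform", "low": 4.0, "high": 6.25},
  "avg_salary": {"dist": "loguniform", "low": 44.0, "high": 68.75},
  "staff_count": {"dist": "uniform", "low": 4.8, "high": 7.5},
  "overhead_cost": {"dist": "loguniform", "low": 40.0, "high": 62.5},
  "expiry_inflow_base": {"dist": "loguniform", "low": 32.0, "high": 50.0},
  "resident_overprescription_coeff": {"dist": "loguniform", "low": 1.6, "high": 2.5},
  "expiry_fraction": {"dist": "uniform", "low": 0.048, "high": 0.075},
  "transfer_rate_coeff": {"dist": "uniform", "low": 0.032, "high": 0.05},
  "monthly_purchase": {"dist": "loguniform", "low": 800.0, "high": 1250.0},
  "share_high_consumption": {"dist": "uniform", "low": 0.36, "high": 0.5625},
  "order_delay": {"dist": "loguniform", "low": 1.2, "high": 1.875},
  "demand_high_base": {"dist": "loguniform", "low": 320.0, "high": 500.0},
  "demand_seasonal_amplitude": {"dist": "uniform", "low": 0.16, "high": 0.25},
  "demand_period": {"dist": "loguniform", "low": 4.8, "high": 7.5},
  "resident_intake_rate": {"dist": "loguniform", "low": 1.2, "high": 1.875},
  "residency_duration": {"dist": "loguniform", "low": 19.2, "high": 30.0}
}
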