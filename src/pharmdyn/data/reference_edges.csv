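source,target,polarity
no_financial_manager,liquidity_problems,1
liquidity_problems,poor_cost_analysis,1
poor_cost_analysis,no_financial_manager,1
poor_cost_analysis,weak_financial_analysis,1
weak_financial_analysis,liquidity_problems,1
weak_financial_analysis,poor_cost_analysis,1
poor_emergency_response,incorrect_prioritization,1
incorrect_prioritization,weak_consumption_analysis,1
weak_consumption_analysis,liquidity_problems,1
liquidity_problems,reduced_profitability,1
reduced_profitability,recruitment_pressure,1
recruitment_pressure,poor_emergency_response,-1
recruitment_pressure,insufficient_staff,-1
insufficient_staff,poor_emergency_response,1
drug_shortages,poor_supplier_relations,1
poor_supplier_relations,drug_shortages,1
medication_expiration,weak_inventory_control,1
weak_inventory_control,medication_expiration,1
medication_expiration,disposal_waste,1
disposal_waste,medication_expiration,1
resident_overprescribing,medication_expiration,1
inadequate_training,insufficient_staff,1
disposal_waste,poor_cost_analysis,1
poor_emergency_response,drug_shortages,1
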