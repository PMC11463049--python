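id,label,role
insufficient_staff,Insufficient specialized human resources,cause
poor_emergency_response,Poor responsiveness in emergencies,cause
resident_overprescribing,Unnecessary prescription of drugs by residents,cause
weak_financial_analysis,Weaknesses in financial analysis,cause
no_financial_manager,Lack of a certified financial manager,cause
incorrect_prioritization,Incorrect prioritization in drug procurement,cause
weak_consumption_analysis,Weak analysis of drug consumption patterns,cause
poor_supplier_relations,Poor relations with suppliers and distributors,cause
weak_inventory_control,Weak drug inventory control,cause
inadequate_training,Inadequate staff training,cause
medication_expiration,Expiration of certain medications,effect
disposal_waste,Accumulation of disposed medicines,effect
liquidity_problems,Inadequate liquidity management,effect
poor_cost_analysis,Weak cost-profitability analysis,effect
reduced_profitability,Reduced pharmacy profitability,effect
recruitment_pressure,Pressure on personnel sufficiency and recruitment,effect
drug_shortages,Shortages of high-consumption drugs,effect
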