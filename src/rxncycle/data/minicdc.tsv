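!!SBtab TableID='ReactionList' TableType='ReactionList' Version='1.0'
!UID:Reaction	!ComponentA:Name	!ComponentA:Domain	!ComponentA:Residue	!Reaction	!ComponentB:Name	!ComponentB:Domain	!ComponentB:Residue	!Tags
R1	SBF			trsc	Cln			
R2	Ribo			trsl	Cln			
R3	Prt			deg	ClnmRNA			
R4	Prt			deg	Cln			
R5	Cdk	cyc1		ppi+	Cln	cdk		
R6	Mcm1			trsc	Clb			
R7	Ribo			trsl	Clb			
R8	Prt			deg	ClbmRNA			
R9	Prt			deg	Clb			
R10	Cdk	cyc2		ppi+	Clb	cdk		
R11	Swi5			trsc	Exit			
R12	Ribo			trsl	Exit			
R13	Prt			deg	ExitmRNA			
R14	Prt			deg	Exit			
R15	Ribo			syn	Sic			
R16	Prt			deg	Sic			
R17	Sic	cdk		ppi+	Cdk	inh		
R18	Cdk			p+	Sic		t	
R19	Ygp1	b		ppi+	Ygp2	b		no-turnover
R20	DNAlic			mt	DNArep			
R21	DNArep			mt	DNAdone			replication
R22	DNAdone			mt	DNAseg			
R23	DNAseg			mt	DNAlic			
R24	SPBsat			mt	SPBdup			
R25	SPBdup			mt	SPBsep			
R26	SPBsep			mt	SPBsat			
R27	BUD0			mt	BUDsmall			
R28	BUDsmall			mt	BUDlarge			
R29	BUDlarge			mt	BUDdiv			
R30	BUDdiv			mt	BUD0			

!!SBtab TableID='ContingencyList' TableType='ContingencyList' Version='1.0'
!UID:Contingency	!Target	!Contingency	!Modifier
C1	SBF_trsc_Cln	[Nutrients]	!
C2	SBF_trsc_Cln	[Pheromone]	x
C3	Mcm1_trsc_Clb	[DNAdone]	!
C4	<exitOK>	[DNAseg]	AND
C5	<exitOK>	[SPBsep]	AND
C6	Swi5_trsc_Exit	<exitOK>	!
C7	Prt_deg_Sic	Sic_[t]-P	!
C8	Sic_[cdk]_ppi+_Cdk_[inh]	Sic_[t]-P	x
C9	Cdk_p+_Sic_[t]	Cdk_[cyc1]--Cln_[cdk]	!
C10	DNAlic_mt_DNArep	[DNAlic]	!
C11	DNAlic_mt_DNArep	Cdk_[cyc1]--Cln_[cdk]	!
C12	DNAlic_mt_DNArep	Cdk_[inh]--Sic_[cdk]	x
C13	DNArep_mt_DNAdone	[DNArep]	!
C14	DNArep_mt_DNAdone	[Histones]	!
C15	DNArep_mt_DNAdone	[HU]	x
C16	DNAdone_mt_DNAseg	[DNAdone]	!
C17	DNAdone_mt_DNAseg	Cdk_[cyc2]--Clb_[cdk]	!
C18	DNAdone_mt_DNAseg	Cdk_[inh]--Sic_[cdk]	x
C19	DNAdone_mt_DNAseg	[NOC]	x
C20	DNAseg_mt_DNAlic	[DNAseg]	!
C21	DNAseg_mt_DNAlic	Exit	!
C22	SPBsat_mt_SPBdup	[SPBsat]	!
C23	SPBsat_mt_SPBdup	Cdk_[cyc1]--Cln_[cdk]	!
C24	SPBsat_mt_SPBdup	Cdk_[inh]--Sic_[cdk]	x
C25	SPBdup_mt_SPBsep	[SPBdup]	!
C26	SPBdup_mt_SPBsep	Cdk_[cyc2]--Clb_[cdk]	!
C27	SPBdup_mt_SPBsep	Cdk_[inh]--Sic_[cdk]	x
C28	SPBsep_mt_SPBsat	[SPBsep]	!
C29	SPBsep_mt_SPBsat	Exit	!
C30	BUD0_mt_BUDsmall	[BUD0]	!
C31	BUD0_mt_BUDsmall	Cdk_[cyc1]--Cln_[cdk]	!
C32	BUD0_mt_BUDsmall	Cdk_[inh]--Sic_[cdk]	x
C33	BUD0_mt_BUDsmall	[LatA]	x
C34	BUDsmall_mt_BUDlarge	[BUDsmall]	!
C35	BUDsmall_mt_BUDlarge	Cdk_[cyc2]--Clb_[cdk]	!
C36	BUDsmall_mt_BUDlarge	[LatA]	x
C37	BUDlarge_mt_BUDdiv	[BUDlarge]	!
C38	BUDlarge_mt_BUDdiv	Exit	!
C39	BUDdiv_mt_BUD0	[BUDdiv]	!

!!SBtab TableID='SettingsList' TableType='SettingsList' Version='1.0'
!Node	!Value
[DNAlic]	true
[SPBsat]	true
[BUD0]	true
[Histones]	true
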