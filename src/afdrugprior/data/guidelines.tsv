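# Drugs with an existing AF-management guideline indication and the
# guideline regions. Bepridil is recommended in the Japanese guideline;
# the remaining drugs appear in the European/American guidelines.
Amiodarone	EUROPE;AMERICA
Atenolol	EUROPE;AMERICA
Bepridil	JAPAN
Bisoprolol	EUROPE;AMERICA
Carvedilol	EUROPE;AMERICA
Disopyramide	EUROPE;AMERICA
Dofetilide	EUROPE;AMERICA
Dronedarone	EUROPE;AMERICA
Esmolol	EUROPE;AMERICA
Flecainide	EUROPE;AMERICA
Ibutilide	EUROPE;AMERICA
Landiolol	EUROPE;AMERICA
Metoprolol	EUROPE;AMERICA
Nadolol	EUROPE;AMERICA
Nebivolol	EUROPE;AMERICA
Procainamide	EUROPE;AMERICA
Propafenone	EUROPE;AMERICA
Propranolol	EUROPE;AMERICA
Quinidine	EUROPE;AMERICA
Sotalol	EUROPE;AMERICA
Vernakalant	EUROPE;AMERICA
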