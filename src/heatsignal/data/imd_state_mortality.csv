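period,region,source,deaths
2010,Andhra Pradesh,IMD,75
2011,Andhra Pradesh,IMD,0
2012,Andhra Pradesh,IMD,5
2013,Andhra Pradesh,IMD,442
2014,Andhra Pradesh,IMD,0
2015,Andhra Pradesh,IMD,1722
2010,Telangana,IMD,0
2011,Telangana,IMD,0
2012,Telangana,IMD,0
2013,Telangana,IMD,0
2014,Telangana,IMD,0
2015,Telangana,IMD,585
2010,Maharashtra,IMD,158
2011,Maharashtra,IMD,1
2012,Maharashtra,IMD,1
2013,Maharashtra,IMD,5
2014,Maharashtra,IMD,0
2015,Maharashtra,IMD,0
2010,Odisha,IMD,33
2011,Odisha,IMD,0
2012,Odisha,IMD,30
2013,Odisha,IMD,4
2014,Odisha,IMD,47
2015,Odisha,IMD,41
2010,West Bengal,IMD,18
2011,West Bengal,IMD,0
2012,West Bengal,IMD,11
2013,West Bengal,IMD,5
2014,West Bengal,IMD,4
2015,West Bengal,IMD,0
2010,Jharkhand,IMD,19
2011,Jharkhand,IMD,0
2012,Jharkhand,IMD,7
2013,Jharkhand,IMD,6
2014,Jharkhand,IMD,0
2015,Jharkhand,IMD,0
2010,Chattisgarh,IMD,9
2011,Chattisgarh,IMD,0
2012,Chattisgarh,IMD,3
2013,Chattisgarh,IMD,0
2014,Chattisgarh,IMD,0
2015,Chattisgarh,IMD,0
2010,Madhya Pradesh,IMD,9
2011,Madhya Pradesh,IMD,0
2012,Madhya Pradesh,IMD,0
2013,Madhya Pradesh,IMD,3
2014,Madhya Pradesh,IMD,0
2015,Madhya Pradesh,IMD,0
2010,Kerala,IMD,2
2011,Kerala,IMD,3
2012,Kerala,IMD,0
2013,Kerala,IMD,3
2014,Kerala,IMD,0
2015,Kerala,IMD,0
2010,Uttar Pradesh,IMD,3
2011,Uttar Pradesh,IMD,0
2012,Uttar Pradesh,IMD,0
2013,Uttar Pradesh,IMD,5
2014,Uttar Pradesh,IMD,0
2015,Uttar Pradesh,IMD,0
2010,Gujarat,IMD,1
2011,Gujarat,IMD,0
2012,Gujarat,IMD,0
2013,Gujarat,IMD,0
2014,Gujarat,IMD,0
2015,Gujarat,IMD,7
2010,Punjab,IMD,0
2011,Punjab,IMD,0
2012,Punjab,IMD,0
2013,Punjab,IMD,6
2014,Punjab,IMD,0
2015,Punjab,IMD,0
2010,Haryana,IMD,0
2011,Haryana,IMD,0
2012,Haryana,IMD,0
2013,Haryana,IMD,2
2014,Haryana,IMD,0
2015,Haryana,IMD,2
2010,Rajasthan,IMD,7
2011,Rajasthan,IMD,0
2012,Rajasthan,IMD,0
2013,Rajasthan,IMD,0
2014,Rajasthan,IMD,0
2015,Rajasthan,IMD,0
2010,Bihar,IMD,3
2011,Bihar,IMD,0
2012,Bihar,IMD,0
2013,Bihar,IMD,0
2014,Bihar,IMD,0
2015,Bihar,IMD,0
2010,Chandigarh,IMD,0
2011,Chandigarh,IMD,1
2012,Chandigarh,IMD,1
2013,Chandigarh,IMD,0
2014,Chandigarh,IMD,0
2015,Chandigarh,IMD,0
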