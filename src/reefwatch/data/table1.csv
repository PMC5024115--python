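reef_name,country,lat,lon,reef_area_km2,island_area_km2,new_area_km2,start,end
Mischief Reef,C,9.90,115.54,13.8,6.39,6.39,Jan 2015,Dec 2015
Subi Reef,C,10.93,114.08,7.12,4.43,4.43,Feb 2015,Nov 2015
Fiery Cross Reef,C,9.55,112.89,4.41,3.06,3.06,Aug 2014,June 2015
Cuarteron Reef,C,8.86,112.83,5.07,0.25,0.25,Mar 2014,Dec 2014
Gaven Reef,C,10.21,114.22,1.83,0.19,0.19,May 2014,Jan 2015
Johnson South Reef,C,9.71,114.29,6.81,0.11,0.11,Feb 2014,Jul 2014
Hughes Reef,C,9.91,114.50,2.59,0.09,0.09,Apr 2014,Jun 2014
Spratly Island,V,8.65,111.92,0.45,0.33,0.17,Feb 2015,Ongoing
Sin Cowe Island,V,9.88,114.33,1.09,0.17,0.11,Apr 2014,Feb 2015
Cornwallis South Reef,V,8.69,114.19,14.98,0.12,0.12,Apr 2015,Ongoing
West Reef,V,8.87,112.25,0.61,0.10,0.10,Pre-OLI,Dec 2015
Sand Cay,V,10.38,114.48,1.18,0.07,0.02,Pre-OLI,Nov 2013
Pearson Reef,V,8.98,113.71,10.32,0.04,<0.01,Feb 2015,Mar 2016
Central Reef,V,8.93,112.35,0.97,0.03,<0.01,Pre-OLI,Dec 2015
Itu Aba Island,T,10.38,114.37,1.57,0.49,0.06,Mar 2014,Oct 2015
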